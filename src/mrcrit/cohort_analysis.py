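"""Cohort-level statistics on the logarithmic distance to criticality.

All group comparisons operate on ``epsilon = log(1 - m_hat)`` rather
than on ``m_hat`` itself, whose distribution near criticality is heavily
skewed. The analyses mirror a within-patient design:

* hemispheric contrast (epileptogenic vs contralateral hemisphere) via a
  linear mixed model ``epsilon ~ focus + (1 | patient_id)``, overall and
  per MTL subregion with Bonferroni control over the four subregions;
* per-patient hemispheric contrasts via the two-sided Mann-Whitney U
  test across that patient's recordings;
* pre-seizure change via a split of each 10-minute epoch into halves and
  a Wilcoxon signed-rank test pairing the two halves of each recording;
* pre-seizure variability change via the median absolute deviation (MAD)
  of the time-resolved ``epsilon(t)`` within each half, again compared
  with the signed-rank test across recordings.

Supercritical estimates (``m_hat >= 1``, epsilon undefined) are excluded
from the epsilon-based tests; their count is reported, never hidden.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mr_estimator import EstimationConfig, InsufficientDataError, estimate_m
from .process_model import ActivityTrace
from .spike_data import (
    RecordingRecord,
    SUBREGIONS,
    read_manifest,
    read_spike_table,
    pool_and_bin,
    results_to_frame,
)
from .timeresolved import WindowConfig, sliding_estimates

__all__ = [
    "ComparisonResult",
    "VariabilityResult",
    "CohortConfig",
    "CohortResults",
    "split_halves",
    "paired_signed_rank",
    "mad_of_series",
    "fit_group_model",
    "bonferroni_gate",
    "mann_whitney_contrast",
    "run_cohort",
    "N_SUBREGION_TESTS",
]

#: Bonferroni divisor for the per-subregion contrasts (H, A, PHC, EC).
N_SUBREGION_TESTS = 4


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one group contrast on epsilon."""

    contrast: str
    n: int                       # usable pairs or observations
    effect: float                # median paired difference, or model coefficient
    statistic: float
    p_value: float
    adjusted_alpha: float = math.nan
    n_dropped: int = 0           # pairs lost to undefined epsilon

    @property
    def significant(self) -> bool:
        alpha = 0.05 if math.isnan(self.adjusted_alpha) else self.adjusted_alpha
        return self.p_value < alpha


@dataclass(frozen=True)
class VariabilityResult:
    """MAD of epsilon(t) in the two halves, compared across recordings."""

    mad_first: float    # median across recordings of the first-half MAD
    mad_second: float
    comparison: ComparisonResult


def split_halves(trace: ActivityTrace) -> tuple[ActivityTrace, ActivityTrace]:
    """Split an epoch into its first and second half.

    For a 600 s pre-seizure epoch these are the earlier 5 minutes and the
    last 5 minutes before seizure onset. With an odd bin count the first
    half receives the extra bin.
    """
    n = len(trace)
    cut = (n + 1) // 2
    first = ActivityTrace(trace.counts[:cut], trace.bin_size, trace.start_time,
                          {**dict(trace.meta), "half": 1})
    second = ActivityTrace(trace.counts[cut:], trace.bin_size,
                           trace.start_time + cut * trace.bin_size,
                           {**dict(trace.meta), "half": 2})
    return first, second


def paired_signed_rank(
    eps_a: Sequence[float],
    eps_b: Sequence[float],
    contrast: str = "paired",
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired epsilon values.

    Pairs with an undefined value (None/NaN, e.g. a supercritical
    estimate) are dropped and counted. Zero differences are dropped
    before ranking (classical convention). The exact null is used for up
    to 25 non-zero pairs without ties; with tied absolute differences
    the null is enumerated by sign flips for up to 16 pairs; the
    tie-corrected normal approximation covers the rest.
    """
    a = np.array([math.nan if v is None else float(v) for v in eps_a])
    b = np.array([math.nan if v is None else float(v) for v in eps_b])
    if a.size != b.size:
        raise ValueError("paired lists must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    n_dropped = int(np.sum(~ok))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise InsufficientDataError(f"{contrast}: fewer than 2 usable pairs")
    diff = b - a
    effect = float(np.median(diff))
    nz = diff[diff != 0]
    if nz.size == 0:
        return ComparisonResult(contrast, int(a.size), 0.0, 0.0, 1.0, n_dropped=n_dropped)
    no_ties = np.unique(np.abs(nz)).size == nz.size
    if nz.size <= 25 and no_ties:
        method = "exact"
    elif nz.size <= 16:
        # full sign-flip enumeration (2^n <= n_resamples => deterministic)
        method = stats.PermutationMethod(n_resamples=2**16)
    else:
        method = "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method=method,
    )
    return ComparisonResult(
        contrast, int(a.size), effect, float(res.statistic), float(res.pvalue),
        n_dropped=n_dropped,
    )


def mann_whitney_contrast(
    eps_a: Sequence[float],
    eps_b: Sequence[float],
    contrast: str = "unpaired",
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test on two unpaired epsilon samples
    (used for the within-patient hemispheric contrast across that
    patient's recordings)."""
    a = np.asarray([v for v in eps_a if v is not None and not math.isnan(v)], dtype=float)
    b = np.asarray([v for v in eps_b if v is not None and not math.isnan(v)], dtype=float)
    n_dropped = (len(eps_a) - a.size) + (len(eps_b) - b.size)
    if a.size < 1 or b.size < 1:
        raise InsufficientDataError(f"{contrast}: empty sample")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    effect = float(np.median(b) - np.median(a))
    return ComparisonResult(
        contrast, int(a.size + b.size), effect, float(res.statistic), float(res.pvalue),
        n_dropped=int(n_dropped),
    )


def mad_of_series(eps_t: Sequence[float]) -> float:
    """Median absolute deviation from the median of a time-resolved
    epsilon series; undefined (NaN) entries are ignored."""
    vals = np.asarray([v for v in eps_t if v is not None], dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise InsufficientDataError("no defined epsilon values in series")
    return float(np.median(np.abs(vals - np.median(vals))))


def fit_group_model(
    table: pd.DataFrame,
    formula: str = "epsilon ~ focus",
    term: Optional[str] = None,
    group_col: str = "patient_id",
) -> ComparisonResult:
    """Linear mixed model on epsilon with a random intercept per patient.

    ``formula`` gives the fixed-effects part (e.g. ``epsilon ~ focus``,
    ``epsilon ~ focus * subregion``, ``epsilon ~ half``); the random
    structure is always ``(1 | patient_id)``. ``term`` selects which
    fixed-effect coefficient is reported (default: the first
    non-intercept term). The model structure is the contract; the solver
    is an established REML routine. The reported p-value uses a
    t-reference with classical within-group degrees of freedom,
    ``df = n_obs - n_groups - (n_fixed - 1)``: the asymptotic Wald z is
    visibly anticonservative on small cohorts, and this correction
    restores the nominal level while converging to z for large ones.
    """
    import statsmodels.formula.api as smf

    data = table.dropna(subset=["epsilon"]).copy()
    n_dropped = len(table) - len(data)
    if data[group_col].nunique() < 2:
        raise InsufficientDataError(
            "mixed model needs >= 2 patients (random intercept unidentifiable)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[group_col])
        fit = model.fit(reml=True)
    fe = fit.fe_params
    names = [n for n in fe.index if n != "Intercept"]
    if term is None:
        matches = names[:1]
    else:
        matches = [n for n in names if term in n]
    if not matches:
        raise ValueError(f"term {term!r} not found among fixed effects {names}")
    name = matches[0]
    tval = float(fit.tvalues[name])
    df_within = max(len(data) - data[group_col].nunique() - (len(fe) - 1), 1)
    p_value = 2.0 * float(stats.t.sf(abs(tval), df=df_within))
    return ComparisonResult(
        contrast=f"{formula} [{name}]",
        n=int(len(data)),
        effect=float(fe[name]),
        statistic=tval,
        p_value=p_value,
        n_dropped=int(n_dropped),
    )


def bonferroni_gate(
    p_values: Mapping[str, float],
    alpha: float = 0.05,
    n_tests: int = N_SUBREGION_TESTS,
) -> dict[str, bool]:
    """Bonferroni decision per subregion: significant iff
    ``p < alpha / n_tests`` with the fixed divisor 4 for the four MTL
    subregions."""
    if not (1 <= len(p_values) <= n_tests):
        raise ValueError(f"expected 1..{n_tests} p-values, got {len(p_values)}")
    thr = alpha / n_tests
    return {k: (p < thr) for k, p in p_values.items()}


# ---------------------------------------------------------------------------
# Full-cohort orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Subset selection and estimation settings for a cohort run."""

    subset: str = "all"  # all | engel1a | paired
    est_config: EstimationConfig = field(default_factory=lambda: EstimationConfig(n_boot=0))
    window_config: WindowConfig = field(default_factory=WindowConfig)
    include_timeresolved: bool = True
    include_subregions: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.subset not in ("all", "engel1a", "paired"):
            raise ValueError("subset must be all | engel1a | paired")


@dataclass
class CohortResults:
    """Bundle of cohort-level outputs."""

    estimates: pd.DataFrame                      # per recording x hemisphere (x subregion)
    hemispheric: Optional[ComparisonResult]
    hemispheric_by_subregion: dict[str, ComparisonResult]
    subregion_significance: dict[str, bool]
    per_patient: dict[str, ComparisonResult]
    split_half: dict[str, ComparisonResult]      # keyed by hemisphere role (full MTL)
    split_half_by_subregion: dict[tuple[str, str], ComparisonResult]
    variability: Optional[VariabilityResult]
    n_supercritical: int
    skipped: list[str] = field(default_factory=list)  # analyses skipped, with reason


def _subset_manifest(manifest: dict, subset: str) -> set[str]:
    """Patient ids retained under the subset rule."""
    patients = manifest["patients"]
    if subset == "engel1a":
        return {p["patient_id"] for p in patients if str(p.get("engel", "")) == "1a"}
    return {p["patient_id"] for p in patients}


def _eps(res) -> float:
    return math.nan if res.epsilon is None else res.epsilon


def run_cohort(
    manifest: dict | str | Path,
    config: CohortConfig = CohortConfig(),
    records: Optional[Sequence[RecordingRecord]] = None,
) -> CohortResults:
    """Run every cohort-level analysis on a labeled spike dataset.

    ``manifest`` is the manifest mapping (or path to its YAML) listing
    patients, recordings and Engel outcomes; it names the spike table in
    its ``spike_table`` entry unless ``records`` are passed directly.
    Empty or infeasible analyses are skipped with a note in
    ``skipped``; the pipeline always returns the rest.
    """
    manifest_dir = Path(".")
    if not isinstance(manifest, Mapping):
        manifest_dir = Path(manifest).parent
        manifest = read_manifest(manifest)
    if records is None:
        records = read_spike_table(
            manifest_dir / manifest["spike_table"],
            duration=float(manifest.get("duration", 600.0)),
        )

    keep = _subset_manifest(manifest, config.subset)
    records = [r for r in records if r.patient_id in keep]
    if config.subset == "paired":
        # recordings with spikes from both hemispheres of the same patient
        seen: dict[tuple[str, str], set[str]] = {}
        for r in records:
            seen.setdefault((r.patient_id, r.recording_id), set()).add(r.hemisphere_role)
        paired_ids = {k for k, roles in seen.items() if len(roles) == 2}
        records = [r for r in records if (r.patient_id, r.recording_id) in paired_ids]

    skipped: list[str] = []
    n_supercritical = 0

    # --- whole-recording estimates, full MTL per hemisphere -----------------
    mtl_traces = pool_and_bin(records)
    labeled = []
    half_rows = []
    trace_store: dict[tuple, ActivityTrace] = {}
    for key, trace in mtl_traces.items():
        res = estimate_m(trace, config.est_config)
        if res.flags.supercritical:
            n_supercritical += 1
        labels = dict(trace.meta)
        labels.pop("n_units", None)
        labels["subregion"] = "MTL"
        labeled.append((labels, res))
        trace_store[key] = trace
        if labels["epoch_kind"] == "preseizure":
            first, second = split_halves(trace)
            r1 = estimate_m(first, config.est_config)
            r2 = estimate_m(second, config.est_config)
            n_supercritical += int(r1.flags.supercritical) + int(r2.flags.supercritical)
            half_rows.append({**labels, "eps_first": _eps(r1), "eps_second": _eps(r2),
                              "accepted": r1.accepted and r2.accepted})

    # --- per-subregion estimates --------------------------------------------
    if config.include_subregions:
        sub_keys = ("patient_id", "recording_id", "epoch_kind", "hemisphere_role", "subregion")
        for key, trace in pool_and_bin(records, group_keys=sub_keys).items():
            res = estimate_m(trace, config.est_config)
            if res.flags.supercritical:
                n_supercritical += 1
            labels = dict(trace.meta)
            labels.pop("n_units", None)
            labeled.append((labels, res))

    estimates = results_to_frame(labeled)
    est_ok = estimates[estimates["accepted"]]

    # --- hemispheric mixed-model contrast -----------------------------------
    mtl_ok = est_ok[est_ok["subregion"] == "MTL"]
    hemispheric = None
    try:
        hemispheric = fit_group_model(
            mtl_ok.rename(columns={"hemisphere_role": "focus"}),
            "epsilon ~ focus", term="focus",
        )
    except (InsufficientDataError, ValueError) as exc:
        skipped.append(f"hemispheric: {exc}")

    hemispheric_by_subregion: dict[str, ComparisonResult] = {}
    subregion_significance: dict[str, bool] = {}
    if config.include_subregions:
        for sub in SUBREGIONS:
            tab = est_ok[est_ok["subregion"] == sub]
            if tab.empty:
                skipped.append(f"hemispheric[{sub}]: no accepted estimates")
                continue
            try:
                hemispheric_by_subregion[sub] = fit_group_model(
                    tab.rename(columns={"hemisphere_role": "focus"}),
                    "epsilon ~ focus", term="focus",
                )
            except (InsufficientDataError, ValueError) as exc:
                skipped.append(f"hemispheric[{sub}]: {exc}")
        if hemispheric_by_subregion:
            subregion_significance = bonferroni_gate(
                {s: r.p_value for s, r in hemispheric_by_subregion.items()},
                alpha=config.alpha,
            )

    # --- per-patient contrast (unpaired rank-sum across recordings) ---------
    per_patient: dict[str, ComparisonResult] = {}
    for pid, tab in mtl_ok.groupby("patient_id"):
        ipsi = tab.loc[tab["hemisphere_role"] == "ipsilateral", "epsilon"].tolist()
        contra = tab.loc[tab["hemisphere_role"] == "contralateral", "epsilon"].tolist()
        try:
            per_patient[str(pid)] = mann_whitney_contrast(
                contra, ipsi, contrast=f"patient {pid}: ipsi vs contra"
            )
        except InsufficientDataError as exc:
            skipped.append(str(exc))

    # --- split-half pre-seizure comparison ----------------------------------
    halves = pd.DataFrame(half_rows)
    split_half: dict[str, ComparisonResult] = {}
    if not halves.empty:
        for role, tab in halves[halves["accepted"]].groupby("hemisphere_role"):
            try:
                split_half[str(role)] = paired_signed_rank(
                    tab["eps_first"], tab["eps_second"],
                    contrast=f"split-half {role} (MTL)",
                )
            except InsufficientDataError as exc:
                skipped.append(str(exc))
    else:
        skipped.append("split-half: no pre-seizure recordings")

    split_half_by_subregion: dict[tuple[str, str], ComparisonResult] = {}
    if config.include_subregions and records:
        sub_keys = ("patient_id", "recording_id", "epoch_kind", "hemisphere_role", "subregion")
        rows: dict[tuple[str, str], list[tuple[float, float]]] = {}
        for key, trace in pool_and_bin(records, group_keys=sub_keys).items():
            meta = trace.meta
            if meta["epoch_kind"] != "preseizure":
                continue
            first, second = split_halves(trace)
            r1 = estimate_m(first, config.est_config)
            r2 = estimate_m(second, config.est_config)
            if not (r1.accepted and r2.accepted):
                continue
            rows.setdefault((meta["hemisphere_role"], meta["subregion"]), []).append(
                (_eps(r1), _eps(r2))
            )
        for (role, sub), pairs in sorted(rows.items()):
            try:
                split_half_by_subregion[(role, sub)] = paired_signed_rank(
                    [p[0] for p in pairs], [p[1] for p in pairs],
                    contrast=f"split-half {role} ({sub})",
                )
            except InsufficientDataError as exc:
                skipped.append(str(exc))

    # --- MAD variability comparison (time-resolved) -------------------------
    variability = None
    if config.include_timeresolved:
        mads_first, mads_second = [], []
        for key, trace in trace_store.items():
            meta = trace.meta
            if meta["epoch_kind"] != "preseizure" or meta["hemisphere_role"] != "ipsilateral":
                continue
            try:
                series = sliding_estimates(trace, config.window_config, config.est_config)
            except ValueError as exc:
                skipped.append(f"timeresolved {key}: {exc}")
                continue
            if series.excluded_recording:
                skipped.append(f"timeresolved {key}: >5% inconsistent windows")
                continue
            eps = series.epsilon_series()
            mid = series.centers[0] + (series.centers[-1] - series.centers[0]) / 2.0
            first_half = eps[series.centers <= mid]
            second_half = eps[series.centers > mid]
            try:
                mads_first.append(mad_of_series(first_half))
                mads_second.append(mad_of_series(second_half))
            except InsufficientDataError as exc:
                skipped.append(f"timeresolved {key}: {exc}")
        if len(mads_first) >= 2:
            comp = paired_signed_rank(mads_first, mads_second, contrast="MAD first vs second half")
            variability = VariabilityResult(
                mad_first=float(np.median(mads_first)),
                mad_second=float(np.median(mads_second)),
                comparison=comp,
            )
        else:
            skipped.append("variability: fewer than 2 usable recordings")

    return CohortResults(
        estimates=estimates,
        hemispheric=hemispheric,
        hemispheric_by_subregion=hemispheric_by_subregion,
        subregion_significance=subregion_significance,
        per_patient=per_patient,
        split_half=split_half,
        split_half_by_subregion=split_half_by_subregion,
        variability=variability,
        n_supercritical=n_supercritical,
        skipped=skipped,
    )
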