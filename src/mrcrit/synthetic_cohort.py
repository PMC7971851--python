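"""Synthetic patient cohorts with the statistical structure of clinical
single-unit recordings.

Each cohort consists of patients with several 10-minute recording
epochs; in every epoch, each hemisphere (ipsilateral = containing the
putative focus, contralateral = control) contributes four MTL subregions
(H, A, PHC, EC), each generated as an independent driven branching
process, binomially subsampled to emulate the tiny recorded fraction of
neurons, and disaggregated into per-unit spike times. Defaults are
calibrated so the sampled pooled count per 4 ms bin is of order 0.1
(population firing rate in the tens of Hz, >90% empty bins), matching
the clinical medians of ~25.8 Hz and ~9.9% non-zero bins within a
factor of two.

Generative regimes
------------------
``null``
    constant subcritical m everywhere; no programmed difference.
``closer_to_critical`` (scenario A)
    the ipsilateral hemisphere operates at a constant m closer to 1.
``drift`` (scenario B)
    ipsilateral pre-seizure epochs ramp m linearly upward over the final
    ``drift_window`` seconds, emulating a drift towards instability.
``variability_increase``
    ipsilateral pre-seizure epochs jitter m between 20 s blocks in the
    second half of the epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .process_model import (
    ConfigurationError,
    DEFAULT_BIN_SIZE,
    _simulate_ensemble,
    expected_stationary_mean,
    stationary_burnin_bins,
)
from .spike_data import (
    RecordingRecord,
    SUBREGIONS,
    write_manifest,
    write_spike_table,
)

__all__ = ["ScenarioSpec", "scenario_m_profile", "generate_cohort", "SCENARIOS"]

SCENARIOS = ("null", "closer_to_critical", "drift", "variability_increase")

#: clinical calibration targets (dataset medians): pooled per-region
#: firing rate and tolerance factor on the implied mean count per bin
TARGET_RATE_HZ = 25.8
TARGET_NONZERO_FRACTION = 0.099
CALIBRATION_FACTOR = 2.0

_JITTER_BLOCK_SECONDS = 20.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative description of one synthetic cohort."""

    scenario: str = "null"
    n_patients: int = 8
    recordings_per_patient: int = 4     # first epoch is the seizure-free reference
    m_contra: float = 0.95
    m_ipsi: Optional[float] = None      # default: m_contra, or 0.98 for scenario A
    drift_delta: float = 0.04           # terminal rise of m (scenario B)
    drift_window: float = 300.0         # seconds over which m ramps (scenario B)
    variability_sd: float = 0.01        # block-wise sd of m (variability scenario)
    alpha: float = 0.004                # subsampling fraction
    drive_rate: float = 1.0             # mean external input h per bin
    duration: float = 600.0             # seconds per epoch
    bin_size: float = DEFAULT_BIN_SIZE
    n_units: int = 10                   # recorded single units per subregion
    engel_1a_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"scenario must be one of {SCENARIOS}")
        if self.n_patients < 1 or self.recordings_per_patient < 1 or self.n_units < 1:
            raise ConfigurationError("cohort sizes must be >= 1")
        for name, m in (("m_contra", self.m_contra), ("m_ipsi", self.resolved_m_ipsi())):
            if not (0.0 < m < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {m}")
        if self.scenario == "drift":
            terminal = self.resolved_m_ipsi() + self.drift_delta
            if terminal >= 1.0:
                raise ConfigurationError(
                    f"drift ramp reaches m={terminal:.4f} >= 1 (supercritical); "
                    "reduce drift_delta or the baseline"
                )
            if not (0.0 < self.drift_window <= self.duration):
                raise ConfigurationError("drift_window must lie in (0, duration]")
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in [0, 1]")
        if not (0.0 <= self.engel_1a_fraction <= 1.0):
            raise ConfigurationError("engel_1a_fraction must lie in [0, 1]")
        self._check_calibration()

    def resolved_m_ipsi(self) -> float:
        if self.m_ipsi is not None:
            return self.m_ipsi
        return 0.98 if self.scenario == "closer_to_critical" else self.m_contra

    @property
    def duration_bins(self) -> int:
        return int(round(self.duration / self.bin_size))

    def _check_calibration(self) -> None:
        """Sampled pooled count per bin must sit within a factor
        CALIBRATION_FACTOR of the clinical target (rate medians are
        dataset medians, so exact matching is not attempted)."""
        target = TARGET_RATE_HZ * self.bin_size
        expected = self.alpha * expected_stationary_mean(self.m_contra, self.drive_rate)
        if not (target / CALIBRATION_FACTOR <= expected <= target * CALIBRATION_FACTOR):
            raise ConfigurationError(
                f"calibration infeasible: expected sampled count/bin "
                f"{expected:.4f} outside factor-{CALIBRATION_FACTOR} band of "
                f"target {target:.4f} (alpha={self.alpha}, h={self.drive_rate}, "
                f"m={self.m_contra})"
            )


def scenario_m_profile(
    spec: ScenarioSpec,
    role: str,
    epoch_kind: str,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Branching-parameter profile per bin for one epoch.

    Programmed effects (scenario-A offset, scenario-B ramp, variability
    jitter) apply to the ipsilateral hemisphere; reference epochs share
    the pre-seizure baseline.
    """
    T = spec.duration_bins
    base = spec.resolved_m_ipsi() if role == "ipsilateral" else spec.m_contra
    profile = np.full(T, base)
    if role != "ipsilateral" or epoch_kind != "preseizure":
        return profile
    if spec.scenario == "drift":
        ramp_bins = int(round(spec.drift_window / spec.bin_size))
        ramp = np.linspace(0.0, spec.drift_delta, ramp_bins)
        profile[T - ramp_bins:] = base + ramp
    elif spec.scenario == "variability_increase":
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        block = int(round(_JITTER_BLOCK_SECONDS / spec.bin_size))
        half = T // 2
        for lo in range(half, T, block):
            jitter = rng.normal(scale=spec.variability_sd)
            profile[lo : lo + block] = float(np.clip(base + jitter, 1e-3, 0.999))
    return profile


def generate_cohort(
    spec: ScenarioSpec,
    out_dir: Optional[str | Path] = None,
) -> tuple[list[RecordingRecord], dict]:
    """Generate a full synthetic cohort: per-unit spike records plus a
    manifest.

    Every patient x recording x hemisphere x subregion is one simulated
    branching process (burn-in at the baseline m discarded), binomially
    subsampled with ``alpha``; each sampled bin count is disaggregated
    into spikes assigned uniformly at random in time within the bin and
    to units with Dirichlet-distributed weights (uneven single-unit
    rates). Fully seed-deterministic; per-bin spike totals equal the
    sampled counts exactly. When ``out_dir`` is given, ``spikes.tsv``
    and ``manifest.yaml`` are written there.
    """
    root = np.random.default_rng(spec.seed)
    T = spec.duration_bins
    burn_m = max(spec.m_contra, spec.resolved_m_ipsi())
    burnin = stationary_burnin_bins(burn_m, spec.bin_size)

    n_engel = int(round(spec.engel_1a_fraction * spec.n_patients))
    patients = []
    records: list[RecordingRecord] = []

    # Group simulations by identical m-profile so an ensemble call covers
    # all subregions/patients that share it (same recursion per column).
    for p in range(spec.n_patients):
        pid = f"P{p + 1:02d}"
        patient_entry = {
            "patient_id": pid,
            "engel": "1a" if p < n_engel else "2",
            "recordings": [],
        }
        for r in range(spec.recordings_per_patient):
            rid = f"R{r + 1:02d}"
            epoch_kind = "reference" if r == 0 else "preseizure"
            patient_entry["recordings"].append(
                {"recording_id": rid, "epoch_kind": epoch_kind, "duration": spec.duration}
            )
            for role in ("ipsilateral", "contralateral"):
                profile = scenario_m_profile(spec, role, epoch_kind, rng=root)
                full_profile = np.concatenate([np.full(burnin, profile[0]), profile])
                init = int(round(expected_stationary_mean(profile[0], spec.drive_rate)))
                counts = _simulate_ensemble(
                    full_profile,
                    spec.drive_rate,
                    T + burnin,
                    n_traces=len(SUBREGIONS),
                    initial_activity=init,
                    rng=root,
                )[burnin:]
                sampled = root.binomial(counts, spec.alpha)
                for s, sub in enumerate(SUBREGIONS):
                    records.extend(
                        _disaggregate(
                            sampled[:, s], spec, pid, rid, epoch_kind, role, sub, root
                        )
                    )
        patients.append(patient_entry)

    manifest = {
        "scenario": spec.scenario,
        "seed": spec.seed,
        "duration": spec.duration,
        "spike_table": "spikes.tsv",
        "patients": patients,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_spike_table(records, out_dir / "spikes.tsv")
        write_manifest(manifest, out_dir / "manifest.yaml")
    return records, manifest


def _disaggregate(
    sampled_counts: np.ndarray,
    spec: ScenarioSpec,
    patient_id: str,
    recording_id: str,
    epoch_kind: str,
    role: str,
    subregion: str,
    rng: np.random.Generator,
) -> list[RecordingRecord]:
    """Turn per-bin sampled counts into per-unit spike-time records."""
    weights = rng.dirichlet(np.ones(spec.n_units))
    bin_idx = np.repeat(np.arange(sampled_counts.size), sampled_counts)
    n_spikes = bin_idx.size
    units = rng.choice(spec.n_units, size=n_spikes, p=weights)
    times = (bin_idx + rng.uniform(size=n_spikes)) * spec.bin_size
    # guard against float rounding pushing a spike onto the epoch edge
    times = np.minimum(times, np.nextafter(spec.duration, 0.0))
    out = []
    for u in range(spec.n_units):
        ut = np.sort(times[units == u])
        if ut.size == 0:
            continue
        out.append(
            RecordingRecord(
                patient_id=patient_id,
                recording_id=recording_id,
                epoch_kind=epoch_kind,
                hemisphere_role=role,
                subregion=subregion,
                unit_id=f"{subregion}-u{u + 1:02d}",
                spike_times=ut,
                duration=spec.duration,
            )
        )
    return out
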