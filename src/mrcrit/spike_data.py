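"""Spike-event tables: reading, pooling, binning, and result output.

Input format is a tab-separated table with one row per spike and header
columns ``patient_id, recording_id, epoch_kind, hemisphere_role,
subregion, unit_id, quality, spike_time_s``. Hemispheres are labeled by
their role relative to the clinically determined epileptic focus
(ipsilateral / contralateral), and subregions are the four medial
temporal lobe (MTL) areas: hippocampus (H), amygdala (A),
parahippocampal cortex (PHC), entorhinal cortex (EC). Only single units
(``quality == "single"``) enter the analysis.

Pooling sums spikes across the units of a group (per hemisphere over the
full MTL, or per hemisphere and subregion) and bins them into half-open
4 ms bins ``[i*dt, (i+1)*dt)`` to produce the population activity trace.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .mr_estimator import MrResult
from .process_model import ActivityTrace, DEFAULT_BIN_SIZE

__all__ = [
    "RecordingRecord",
    "SPIKE_TABLE_COLUMNS",
    "EPOCH_KINDS",
    "HEMISPHERE_ROLES",
    "SUBREGIONS",
    "read_spike_table",
    "write_spike_table",
    "pool_and_bin",
    "results_to_frame",
    "write_results",
    "read_manifest",
    "write_manifest",
]

SPIKE_TABLE_COLUMNS = (
    "patient_id",
    "recording_id",
    "epoch_kind",
    "hemisphere_role",
    "subregion",
    "unit_id",
    "quality",
    "spike_time_s",
)

EPOCH_KINDS = ("reference", "preseizure")
HEMISPHERE_ROLES = ("ipsilateral", "contralateral")
SUBREGIONS = ("H", "A", "PHC", "EC")
DEFAULT_EPOCH_SECONDS = 600.0  # 10-minute epochs

#: quality labels excluded from analysis (single units only)
_EXCLUDED_QUALITIES = ("artifact", "multi-unit")


class SpikeTableError(ValueError):
    """Malformed spike table."""


@dataclass(frozen=True)
class RecordingRecord:
    """Spike times of one unit within one labeled recording epoch."""

    patient_id: str
    recording_id: str
    epoch_kind: str
    hemisphere_role: str
    subregion: str
    unit_id: str
    spike_times: np.ndarray  # seconds from epoch start, sorted
    duration: float = DEFAULT_EPOCH_SECONDS

    def __post_init__(self) -> None:
        if self.epoch_kind not in EPOCH_KINDS:
            raise SpikeTableError(f"epoch_kind must be one of {EPOCH_KINDS}, got {self.epoch_kind!r}")
        if self.hemisphere_role not in HEMISPHERE_ROLES:
            raise SpikeTableError(
                f"hemisphere_role must be one of {HEMISPHERE_ROLES}, got {self.hemisphere_role!r}"
            )
        if self.subregion not in SUBREGIONS:
            raise SpikeTableError(f"subregion must be one of {SUBREGIONS}, got {self.subregion!r}")
        times = np.asarray(self.spike_times, dtype=float)
        if times.ndim != 1:
            raise SpikeTableError("spike_times must be 1-d")
        if times.size and (np.any(np.diff(times) < 0)):
            raise SpikeTableError(f"spike_times of unit {self.unit_id!r} not sorted")
        if times.size and (times[0] < 0 or times[-1] > self.duration):
            raise SpikeTableError(
                f"spike_times of unit {self.unit_id!r} outside [0, {self.duration}]"
            )
        object.__setattr__(self, "spike_times", times)


def read_spike_table(
    path: str | Path,
    duration: float = DEFAULT_EPOCH_SECONDS,
) -> list[RecordingRecord]:
    """Read and validate a spike TSV into per-unit records.

    Units labeled ``artifact`` or ``multi-unit`` in the quality column
    are dropped (single units only). Malformed rows raise with the
    offending field and 1-based line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in SPIKE_TABLE_COLUMNS[:-1]})
    missing = set(SPIKE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise SpikeTableError(f"{path}: missing columns {sorted(missing)}")

    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = times.isna() if len(df) else pd.Series(dtype=bool)
    if len(df) and bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise SpikeTableError(f"{path}:{line}: non-numeric spike_time_s")
    df = df.assign(spike_time_s=times)
    neg = df.index[df["spike_time_s"] < 0]
    if len(neg):
        raise SpikeTableError(f"{path}:{int(neg[0]) + 2}: negative spike_time_s")
    over = df.index[df["spike_time_s"] > duration]
    if len(over):
        raise SpikeTableError(
            f"{path}:{int(over[0]) + 2}: spike_time_s beyond epoch duration {duration}"
        )
    for col, allowed in (
        ("epoch_kind", EPOCH_KINDS),
        ("hemisphere_role", HEMISPHERE_ROLES),
        ("subregion", SUBREGIONS),
    ):
        bad_rows = df.index[~df[col].isin(allowed)]
        if len(bad_rows):
            raise SpikeTableError(
                f"{path}:{int(bad_rows[0]) + 2}: invalid {col} {df[col].iloc[bad_rows[0]]!r}"
            )

    df = df[~df["quality"].isin(_EXCLUDED_QUALITIES)]
    records = []
    unit_keys = ["patient_id", "recording_id", "epoch_kind", "hemisphere_role", "subregion", "unit_id"]
    for key, grp in df.groupby(unit_keys, sort=True):
        records.append(
            RecordingRecord(
                *key,
                spike_times=np.sort(grp["spike_time_s"].to_numpy()),
                duration=duration,
            )
        )
    return records


def write_spike_table(records: Iterable[RecordingRecord], path: str | Path) -> None:
    """Write records as a spike TSV (inverse of :func:`read_spike_table`)."""
    rows = []
    for rec in records:
        for t in rec.spike_times:
            rows.append(
                (
                    rec.patient_id,
                    rec.recording_id,
                    rec.epoch_kind,
                    rec.hemisphere_role,
                    rec.subregion,
                    rec.unit_id,
                    "single",
                    repr(float(t)),
                )
            )
    df = pd.DataFrame(rows, columns=SPIKE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def pool_and_bin(
    records: Sequence[RecordingRecord],
    group_keys: Sequence[str] = ("patient_id", "recording_id", "epoch_kind", "hemisphere_role"),
    bin_size: float = DEFAULT_BIN_SIZE,
    duration: Optional[float] = None,
) -> dict[tuple, ActivityTrace]:
    """Pool spikes across the units of each group and bin to activity.

    ``counts[i]`` is the number of spikes with time in the half-open bin
    ``[i*dt, (i+1)*dt)``, all units pooled. A spike at exactly the epoch
    end is assigned to the last bin only when the duration is an exact
    bin multiple; otherwise it is rejected. Pool over
    ``("patient_id", "recording_id", "epoch_kind", "hemisphere_role")``
    for full-MTL traces or append ``"subregion"`` for per-subregion ones.
    """
    if not records:
        return {}
    unknown = set(group_keys) - {f.name for f in dc_fields(RecordingRecord)}
    if unknown:
        raise ValueError(f"unknown group keys {sorted(unknown)}")

    groups: dict[tuple, list[RecordingRecord]] = {}
    for rec in records:
        key = tuple(getattr(rec, k) for k in group_keys)
        groups.setdefault(key, []).append(rec)

    out: dict[tuple, ActivityTrace] = {}
    for key, recs in sorted(groups.items()):
        durations = {rec.duration for rec in recs}
        if len(durations) > 1:
            raise ValueError(f"group {key}: mixed durations {sorted(durations)}")
        dur = duration if duration is not None else durations.pop()
        n_bins = int(round(dur / bin_size))
        exact = math.isclose(n_bins * bin_size, dur, rel_tol=0, abs_tol=1e-9)
        if not exact:
            n_bins = int(math.floor(dur / bin_size))
        times = np.concatenate([rec.spike_times for rec in recs]) if recs else np.empty(0)
        idx = np.floor(times / bin_size).astype(np.int64)
        at_end = times == dur
        if at_end.any():
            if exact:
                idx[at_end] = n_bins - 1  # closed right edge of the final bin
            else:
                raise ValueError(
                    f"group {key}: spike at t={dur} but duration is not a bin multiple"
                )
        if idx.size and idx.max() >= n_bins:
            raise ValueError(f"group {key}: spike beyond the binned duration")
        counts = np.bincount(idx, minlength=n_bins)
        meta = dict(zip(group_keys, key))
        meta["n_units"] = len(recs)
        out[key] = ActivityTrace(counts, bin_size=bin_size, meta=meta)
    return out


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

_RESULT_FIELDS = (
    "m_hat",
    "tau",
    "epsilon",
    "B",
    "D",
    "sse",
    "ci_low",
    "ci_high",
    "n_nonzero",
    "enough_nonzero",
    "exp_beats_linear",
    "supercritical",
    "accepted",
)


def results_to_frame(results: Mapping[str, MrResult] | Sequence[tuple[Mapping, MrResult]]) -> pd.DataFrame:
    """Flatten MrResults (keyed by label or paired with label dicts) to a
    tidy DataFrame; undefined epsilon (supercritical) becomes NaN."""
    rows = []
    items = results.items() if isinstance(results, Mapping) else results
    for label, res in items:
        row = dict(label) if isinstance(label, Mapping) else {"label": label}
        row.update(
            m_hat=res.m_hat,
            tau=res.tau,
            epsilon=math.nan if res.epsilon is None else res.epsilon,
            B=res.fit.B,
            D=res.fit.D,
            sse=res.fit.sse,
            ci_low=res.ci_low,
            ci_high=res.ci_high,
            n_nonzero=res.n_nonzero,
            enough_nonzero=res.flags.enough_nonzero,
            exp_beats_linear=res.flags.exp_beats_linear,
            supercritical=res.flags.supercritical,
            accepted=res.accepted,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results, path: str | Path, format: str = "tsv") -> None:
    """Write an MrResult table (or any tidy frame) as TSV or JSON.

    Numeric fields round-trip at full precision (``repr`` format); NaN is
    serialized as an explicit ``null`` in JSON. Empty results are an
    error, never a silent empty file.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = results_to_frame(results)
    if df.empty:
        raise ValueError("refusing to write empty results")
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format=None)
    elif format == "json":
        records = df.to_dict(orient="records")
        cleaned = [
            {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in row.items()}
            for row in records
        ]
        path.write_text(json.dumps(cleaned, indent=1, default=str) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Manifest (recording metadata incl. Engel surgical outcome)
# ---------------------------------------------------------------------------

def write_manifest(manifest: Mapping, path: str | Path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(dict(manifest), sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "patients" not in data:
        raise ValueError(f"{path}: manifest must be a mapping with a 'patients' entry")
    return data
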