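"""Sliding-window MR estimation across an epoch.

An 80 s window advanced in 2 s steps trades temporal resolution against
estimation variance; each window's estimate is assigned to the window
midpoint. Windows are anchored at the epoch start and only complete
windows are used. A recording in which more than 5% of windows fail the
estimation consistency checks is flagged for exclusion (the window
results are kept for inspection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .mr_estimator import (
    ConsistencyFlags,
    EstimationConfig,
    ExpFit,
    FitFailureError,
    MrResult,
    ZeroVarianceError,
    estimate_m,
)
from .process_model import ActivityTrace

__all__ = [
    "WindowConfig",
    "WindowedSeries",
    "n_windows",
    "sliding_estimates",
    "apply_recording_exclusion",
    "MAX_INCONSISTENT_FRACTION",
]

#: A recording is excluded when more than this fraction of its windows is
#: inconsistent with the requirements for MR estimation.
MAX_INCONSISTENT_FRACTION = 0.05


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: length ``L_w`` and step ``L_step`` (s)."""

    window_length: float = 80.0
    window_step: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.window_step <= self.window_length):
            raise ValueError("require 0 < window_step <= window_length")


@dataclass(frozen=True)
class WindowedSeries:
    """Per-window MR results with midpoint time stamps."""

    centers: np.ndarray            # window midpoints, seconds
    results: tuple[MrResult, ...]  # one per window
    window_config: WindowConfig
    fraction_inconsistent: float = math.nan
    excluded_recording: bool = False

    def __len__(self) -> int:
        return len(self.results)

    def m_series(self) -> np.ndarray:
        return np.array([r.m_hat for r in self.results])

    def epsilon_series(self) -> np.ndarray:
        """epsilon(t) with NaN at supercritical windows."""
        return np.array(
            [math.nan if r.epsilon is None else r.epsilon for r in self.results]
        )

    def accepted_mask(self) -> np.ndarray:
        return np.array([r.accepted for r in self.results], dtype=bool)


def n_windows(duration_s: float, wc: WindowConfig) -> int:
    """Number of complete windows: floor((T - L_w) / L_step) + 1."""
    if duration_s < wc.window_length:
        return 0
    return int(math.floor((duration_s - wc.window_length) / wc.window_step + 1e-9)) + 1


def sliding_estimates(
    trace: ActivityTrace,
    wc: WindowConfig = WindowConfig(),
    est_config: Optional[EstimationConfig] = None,
) -> WindowedSeries:
    """Run MR estimation in every complete sliding window.

    Windows start at the epoch start and advance by ``window_step``; a
    residual tail shorter than one window is discarded. The per-window
    bootstrap is disabled by default (an 80 s window holds too few 20 s
    blocks for a meaningful CI); variability is assessed across windows
    instead.
    """
    if est_config is None:
        est_config = EstimationConfig(n_boot=0)
    total = n_windows(trace.duration, wc)
    if total == 0:
        raise ValueError(
            f"trace spans {trace.duration:.1f} s < window length {wc.window_length} s"
        )
    win_bins = int(round(wc.window_length / trace.bin_size))
    step_bins = int(round(wc.window_step / trace.bin_size))
    centers = np.empty(total)
    results = []
    for i in range(total):
        lo = i * step_bins
        window = ActivityTrace(
            trace.counts[lo : lo + win_bins],
            bin_size=trace.bin_size,
            start_time=trace.start_time + lo * trace.bin_size,
            meta=dict(trace.meta),
        )
        centers[i] = window.start_time + wc.window_length / 2.0
        try:
            results.append(estimate_m(window, est_config))
        except (ZeroVarianceError, FitFailureError):
            # a silent or degenerate window is inconsistent, not fatal
            results.append(_failed_window_result(window))
    series = WindowedSeries(centers=centers, results=tuple(results), window_config=wc)
    return apply_recording_exclusion(series)


def _failed_window_result(window: ActivityTrace) -> MrResult:
    """Placeholder for a window where estimation is impossible (e.g. a
    constant/silent stretch): NaN fit, accepted=False."""
    nan_fit = ExpFit(B=math.nan, tau=math.nan, D=math.nan, m_hat=math.nan,
                     sse=math.nan, converged=False)
    flags = ConsistencyFlags(
        enough_nonzero=window.n_nonzero >= 1000, exp_beats_linear=False
    )
    return MrResult(fit=nan_fit, epsilon=None, ci_low=math.nan, ci_high=math.nan,
                    n_nonzero=window.n_nonzero, flags=flags, accepted=False)


def apply_recording_exclusion(series: WindowedSeries) -> WindowedSeries:
    """Flag the recording when >5% of windows fail the consistency checks.

    ``fraction_inconsistent`` counts windows with ``accepted == False``
    (either too few non-zero bins or exponential not beating linear).
    """
    if len(series) == 0:
        raise ValueError("empty windowed series")
    frac = float(np.mean(~series.accepted_mask()))
    return replace(
        series,
        fraction_inconsistent=frac,
        excluded_recording=frac > MAX_INCONSISTENT_FRACTION,
    )
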