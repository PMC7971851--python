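"""Driven branching process and the subsampling observation model.

The population activity :math:`A_t` (number of active units in time bin
:math:`t` of width ``bin_size``) evolves as

.. math::

    A_{t+1} = \\sum_{i=1}^{A_t} Y_{t,i} + h_t,

where each active unit spawns a random number of successors with mean
``m`` (the branching parameter) and :math:`h_t` is external drive with
mean ``h``. For Poisson offspring and Poisson drive the update reduces to
``A_{t+1} ~ Poisson(m * A_t + h)``, which is how the simulator draws it.
The process is stable (subcritical) for ``m < 1`` with stationary mean
``h / (1 - m)``, critical at ``m = 1``, and unstable beyond.

Electrode recordings observe only a tiny fraction of the population; that
is modeled by independent binomial thinning of each bin's count with
probability ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "ActivityTrace",
    "SubsampleSpec",
    "simulate_branching",
    "subsample_trace",
    "expected_stationary_mean",
    "stationary_burnin_bins",
    "simulate_stationary",
    "simulate_stationary_ensemble",
]

DEFAULT_BIN_SIZE = 0.004  # seconds; spike propagation timescale

_OFFSPRING_MODELS = ("poisson",)


class ConfigurationError(ValueError):
    """Invalid simulation or estimation configuration."""


@dataclass(frozen=True)
class ActivityTrace:
    """Integer activity counts per time bin.

    Parameters
    ----------
    counts:
        Non-negative integer count per bin.
    bin_size:
        Bin width in seconds.
    start_time:
        Time of the left edge of the first bin, seconds.
    meta:
        Free-form provenance labels (patient, hemisphere, ...).
    """

    counts: np.ndarray
    bin_size: float = DEFAULT_BIN_SIZE
    start_time: float = 0.0
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-d sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("counts must be integer-valued")
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not (self.bin_size > 0):
            raise ValueError("bin_size must be positive")
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self) * self.bin_size

    @property
    def n_nonzero(self) -> int:
        """Number of bins with at least one event."""
        return int(np.count_nonzero(self.counts))

    def with_meta(self, **labels: object) -> "ActivityTrace":
        merged = {**dict(self.meta), **labels}
        return ActivityTrace(self.counts, self.bin_size, self.start_time, merged)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a driven branching-process simulation.

    ``m_profile`` may be a scalar (constant branching parameter) or a
    per-bin sequence; offspring generated in bin ``t`` use
    ``m_profile[t]``. ``drive_rate`` is the mean external input per bin.
    """

    m_profile: float | Sequence[float]
    drive_rate: float
    duration_bins: int
    bin_size: float = DEFAULT_BIN_SIZE
    offspring_model: str = "poisson"
    initial_activity: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.offspring_model not in _OFFSPRING_MODELS:
            raise ConfigurationError(
                f"unknown offspring model {self.offspring_model!r}; "
                f"available: {_OFFSPRING_MODELS}"
            )
        if not (isinstance(self.duration_bins, (int, np.integer)) and self.duration_bins >= 1):
            raise ConfigurationError("duration_bins must be a positive integer")
        if not (self.bin_size > 0 and math.isfinite(self.bin_size)):
            raise ConfigurationError("bin_size must be positive and finite")
        if not (math.isfinite(self.drive_rate) and self.drive_rate >= 0):
            raise ConfigurationError("drive_rate must be finite and >= 0")
        if self.initial_activity < 0:
            raise ConfigurationError("initial_activity must be >= 0")
        profile = self.resolved_m_profile()
        if not np.all(np.isfinite(profile)) or (profile < 0).any():
            raise ConfigurationError("m_profile values must be finite and >= 0")

    def resolved_m_profile(self) -> np.ndarray:
        """Branching parameter per bin, broadcast to ``duration_bins``."""
        profile = np.atleast_1d(np.asarray(self.m_profile, dtype=float))
        if profile.size == 1:
            return np.full(self.duration_bins, float(profile[0]))
        if profile.size != self.duration_bins:
            raise ConfigurationError(
                f"m_profile length {profile.size} != duration_bins {self.duration_bins}"
            )
        return profile


@dataclass(frozen=True)
class SubsampleSpec:
    """Binomial-thinning observation model: each event is observed
    independently with probability ``alpha``."""

    alpha: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in [0, 1]")


def simulate_branching(config: SimConfig) -> ActivityTrace:
    """Simulate the driven branching process.

    ``counts[0]`` equals ``config.initial_activity``; each subsequent bin
    is the Poisson offspring of the previous bin's activity (mean
    ``m_profile[t]`` per active unit) plus Poisson external drive (mean
    ``drive_rate``). Identical configs (including seed) give identical
    traces.
    """
    ensemble = _simulate_ensemble(
        config.resolved_m_profile(),
        config.drive_rate,
        config.duration_bins,
        n_traces=1,
        initial_activity=config.initial_activity,
        rng=np.random.default_rng(config.seed),
    )
    meta = {
        "source": "simulate_branching",
        "drive_rate": config.drive_rate,
        "seed": config.seed,
    }
    return ActivityTrace(ensemble[:, 0], bin_size=config.bin_size, meta=meta)


def _simulate_ensemble(
    m_profile: np.ndarray,
    drive_rate: float,
    duration_bins: int,
    n_traces: int,
    initial_activity: int | np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n_traces`` independent runs as one ``(T, n)`` array.

    The recursion is identical to the per-trace simulator; the Poisson
    offspring sum over ``A_t`` units with mean ``m`` collapses to a single
    Poisson(m * A_t) draw, merged with the Poisson(h) drive.
    """
    counts = np.empty((duration_bins, n_traces), dtype=np.int64)
    counts[0] = initial_activity
    current = counts[0].astype(np.float64)
    for t in range(duration_bins - 1):
        current = rng.poisson(m_profile[t] * current + drive_rate).astype(np.float64)
        counts[t + 1] = current
    return counts


def subsample_trace(trace: ActivityTrace, spec: SubsampleSpec) -> ActivityTrace:
    """Binomially thin each bin's count with probability ``spec.alpha``."""
    rng = np.random.default_rng(spec.seed)
    sampled = rng.binomial(trace.counts, spec.alpha)
    meta = {**dict(trace.meta), "alpha": spec.alpha, "subsample_seed": spec.seed}
    return ActivityTrace(sampled, trace.bin_size, trace.start_time, meta)


def expected_stationary_mean(m: float, h: float) -> float:
    """Stationary mean activity ``h / (1 - m)`` of the subcritical process.

    Raises for ``m >= 1`` (no stationary distribution).
    """
    if not (0.0 <= m < 1.0):
        raise ValueError(f"stationary mean requires 0 <= m < 1, got m={m}")
    if h < 0:
        raise ValueError("drive h must be >= 0")
    return h / (1.0 - m)


def stationary_burnin_bins(m: float, bin_size: float = DEFAULT_BIN_SIZE) -> int:
    """Number of initial bins to discard so initialization transients decay.

    Ten intrinsic timescales, ``ceil(10 * tau / bin_size)`` with
    ``tau = -bin_size / log(m)``; zero for ``m = 0``.
    """
    if not (0.0 <= m < 1.0):
        raise ValueError("burn-in defined for 0 <= m < 1")
    if m == 0.0:
        return 0
    tau = -bin_size / math.log(m)
    return int(math.ceil(10.0 * tau / bin_size))


def simulate_stationary(
    m: float,
    h: float,
    duration_bins: int,
    bin_size: float = DEFAULT_BIN_SIZE,
    seed: int = 0,
) -> ActivityTrace:
    """Simulate a stationary subcritical run: start at the rounded
    stationary mean and drop a ten-timescale burn-in."""
    burnin = stationary_burnin_bins(m, bin_size)
    config = SimConfig(
        m_profile=m,
        drive_rate=h,
        duration_bins=duration_bins + burnin,
        bin_size=bin_size,
        initial_activity=int(round(expected_stationary_mean(m, h))),
        seed=seed,
    )
    full = simulate_branching(config)
    counts = full.counts[burnin:]
    return ActivityTrace(counts, bin_size, meta={**dict(full.meta), "m": m, "burnin_bins": burnin})


def simulate_stationary_ensemble(
    m: float,
    h: float,
    duration_bins: int,
    n_traces: int,
    bin_size: float = DEFAULT_BIN_SIZE,
    seed: int = 0,
) -> np.ndarray:
    """Vectorized ensemble of independent stationary runs, ``(T, n)`` counts.

    Used by calibration and power studies where hundreds of replicates are
    needed; semantics per column match :func:`simulate_stationary`.
    """
    burnin = stationary_burnin_bins(m, bin_size)
    rng = np.random.default_rng(seed)
    profile = np.full(duration_bins + burnin, float(m))
    counts = _simulate_ensemble(
        profile,
        h,
        duration_bins + burnin,
        n_traces=n_traces,
        initial_activity=int(round(expected_stationary_mean(m, h))),
        rng=rng,
    )
    return counts[burnin:]
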