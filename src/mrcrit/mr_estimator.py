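"""Multistep-regression (MR) estimation of the branching parameter.

The branching parameter ``m`` of a stationary population-activity process
is inferred in two steps:

1. compute the activity autocorrelation ``C(k)`` over many lags ``k``
   (segment-mean convention: the leading and lagged segments each use
   their own mean),
2. fit an exponential decay with offset,

   .. math:: f(k) = B\\,m^k + D = B\\,e^{-k\\Delta t/\\tau} + D,

   whose decay rate gives ``m_hat = exp(-dt / tau_hat)``.

Spatial subsampling (observing a small fraction of the population) scales
the autocorrelation amplitude — absorbed by ``B`` — but leaves the decay
rate untouched, which is why the multistep fit is subsampling-invariant
while the conventional lag-1 regression slope (``B * m``) is biased low.

Estimates are gated by two consistency checks: at least 1000 non-zero
time bins, and the exponential must fit the autocorrelation better than a
straight line (otherwise the data are not consistent with a stationary
autoregressive representation). Confidence intervals come from a block
bootstrap over 20 s segments using a pooled stationary mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .process_model import ActivityTrace

__all__ = [
    "AcfEstimate",
    "ExpFit",
    "LinearFit",
    "ConsistencyFlags",
    "MrResult",
    "EstimationConfig",
    "compute_acf",
    "fit_exp_offset",
    "fit_linear",
    "check_consistency",
    "estimate_m",
    "bootstrap_ci",
    "log_distance",
    "naive_lag1_slope",
    "default_k_max",
    "MIN_NONZERO_BINS",
]

#: Minimum number of non-zero time bins for a reliable estimate.
MIN_NONZERO_BINS = 1000

#: Default largest lag time in seconds (k in [1 bin, 1.6 s]).
DEFAULT_K_MAX_SECONDS = 1.6

#: Fit bounds in the m-parametrization. The lower bound corresponds to an
#: intrinsic timescale of one tenth of a bin; the upper bound sits
#: slightly above 1 so near- and supercritical windows are expressible.
M_BOUNDS = (math.exp(-10.0), 1.05)
B_BOUNDS = (-1.0, 5.0)
D_BOUNDS = (-1.0, 1.0)


class ZeroVarianceError(ValueError):
    """Autocorrelation undefined: the trace (segment) has no variance."""


class FitFailureError(RuntimeError):
    """The exponential-with-offset fit failed to converge."""


class InsufficientDataError(ValueError):
    """Not enough data for the requested operation."""


def default_k_max(bin_size: float) -> int:
    """Largest lag in bins for the default 4 ms – 1.6 s lag range."""
    return int(math.floor(DEFAULT_K_MAX_SECONDS / bin_size))


@dataclass(frozen=True)
class AcfEstimate:
    """Autocorrelation coefficients ``C(k)`` over an integer lag grid."""

    lags: np.ndarray          # lag in bins, 1..k_max
    coefficients: np.ndarray  # C(k)
    n_used: np.ndarray        # time-point pairs per lag
    bin_size: float

    @property
    def lag_times(self) -> np.ndarray:
        """Lags in seconds."""
        return self.lags * self.bin_size


@dataclass(frozen=True)
class ExpFit:
    """Least-squares fit of ``B * m^k + D`` to an autocorrelation."""

    B: float
    tau: float     # intrinsic timescale, seconds; negative branch if m_hat > 1
    D: float
    m_hat: float   # exp(-bin_size / tau), exactly
    sse: float
    converged: bool = True

    @property
    def supercritical(self) -> bool:
        return self.m_hat >= 1.0


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line through ``(k * dt, C(k))``."""

    slope: float
    intercept: float
    sse: float


@dataclass(frozen=True)
class ConsistencyFlags:
    enough_nonzero: bool
    exp_beats_linear: bool
    supercritical: bool = False
    ci_available: bool = False


@dataclass(frozen=True)
class MrResult:
    """Full outcome of MR estimation on one trace (or window)."""

    fit: ExpFit
    epsilon: Optional[float]      # log(1 - m_hat); None when m_hat >= 1
    ci_low: float                 # bootstrap percentile bounds on m_hat
    ci_high: float                # NaN when the CI is unavailable
    n_nonzero: int
    flags: ConsistencyFlags
    accepted: bool

    @property
    def m_hat(self) -> float:
        return self.fit.m_hat

    @property
    def tau(self) -> float:
        return self.fit.tau


@dataclass(frozen=True)
class EstimationConfig:
    """Settings for :func:`estimate_m`.

    ``k_max_bins=None`` resolves to ``floor(1.6 s / bin_size)``.
    ``linear_comparison`` selects the exponential-vs-linear statistic:
    ``"aic"`` (default; penalizes the exponential's extra parameter so
    flat-noise autocorrelations are not "fit" by a degenerate near-linear
    exponential) or plain ``"sse"``. ``n_boot=0`` disables the bootstrap
    CI.
    """

    k_max_bins: Optional[int] = None
    n_boot: int = 250
    boot_block_seconds: float = 20.0
    ci_level: float = 0.95
    max_restarts: int = 10
    min_fit_attempts: int = 3
    linear_comparison: str = "aic"
    fit_seed: int = 0
    boot_seed: int = 0

    def __post_init__(self) -> None:
        if self.linear_comparison not in ("sse", "aic"):
            raise ValueError("linear_comparison must be 'sse' or 'aic'")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")

    def resolved_k_max(self, bin_size: float) -> int:
        return self.k_max_bins if self.k_max_bins is not None else default_k_max(bin_size)


# ---------------------------------------------------------------------------
# Step 1: autocorrelation
# ---------------------------------------------------------------------------

def compute_acf(trace: ActivityTrace, k_max: int) -> AcfEstimate:
    """Autocorrelation ``C(k)`` for ``k = 1 .. k_max`` bins.

    For each lag the leading segment ``A_1..A_{T-k}`` and the lagged
    segment ``A_{1+k}..A_T`` are demeaned separately:

    ``C(k) = sum (A_t - mean_lead)(A_{t+k} - mean_lag) / sum (A_t - mean_lead)^2``

    which equals the OLS slope of the lag-k regression of ``A_{t+k}`` on
    ``A_t``.
    """
    A = trace.counts.astype(np.float64)
    T = A.size
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max >= T:
        raise ValueError(f"k_max ({k_max}) must be smaller than trace length ({T})")
    if np.all(A == A[0]):
        raise ZeroVarianceError("constant trace: autocorrelation undefined")

    lags = np.arange(1, k_max + 1)
    coeffs = np.empty(k_max, dtype=np.float64)
    n_used = T - lags
    for i, k in enumerate(lags):
        x = A[: T - k]
        y = A[k:]
        n = T - k
        xm = x.mean()
        ym = y.mean()
        num = float(np.dot(x, y)) - n * xm * ym
        den = float(np.dot(x, x)) - n * xm * xm
        if den <= 0.0:
            raise ZeroVarianceError(f"zero variance in leading segment at lag {k}")
        coeffs[i] = num / den
    return AcfEstimate(lags=lags, coefficients=coeffs, n_used=n_used, bin_size=trace.bin_size)


# ---------------------------------------------------------------------------
# Step 2: exponential-with-offset fit
# ---------------------------------------------------------------------------

def _exp_model(params: np.ndarray, k: np.ndarray) -> np.ndarray:
    B, m, D = params
    return B * np.power(m, k) + D


def _residuals(params: np.ndarray, k: np.ndarray, c: np.ndarray) -> np.ndarray:
    return _exp_model(params, k) - c


def _jacobian(params: np.ndarray, k: np.ndarray, c: np.ndarray) -> np.ndarray:
    B, m, D = params
    mk = np.power(m, k)
    jac = np.empty((k.size, 3))
    jac[:, 0] = mk
    jac[:, 1] = B * k * np.power(m, k - 1)
    jac[:, 2] = 1.0
    return jac


def _initial_guess(lags: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Data-driven initials: decay rate from a log-linear regression of the
    offset-removed ACF over the first decade of lags."""
    n_head = max(4, min(lags.size, 10))
    d0 = float(np.mean(coeffs[-max(1, lags.size // 10):]))
    shifted = np.maximum(coeffs[:n_head] - np.min(coeffs), 1e-12)
    slope = np.polyfit(lags[:n_head], np.log(shifted), 1)[0]
    m0 = float(np.clip(math.exp(slope), M_BOUNDS[0] * 1.01, 0.9999))
    b0 = float(np.clip(coeffs[0], B_BOUNDS[0] + 1e-6, B_BOUNDS[1] - 1e-6))
    return np.array([b0, m0, float(np.clip(d0, D_BOUNDS[0] + 1e-6, D_BOUNDS[1] - 1e-6))])


def _clip_to_bounds(params: np.ndarray) -> np.ndarray:
    lo = np.array([B_BOUNDS[0], M_BOUNDS[0], D_BOUNDS[0]])
    hi = np.array([B_BOUNDS[1], M_BOUNDS[1], D_BOUNDS[1]])
    eps = 1e-9
    return np.clip(params, lo + eps, hi - eps)


def fit_exp_offset(
    acf: AcfEstimate,
    bin_size: float,
    max_restarts: int = 10,
    min_attempts: int = 3,
    seed: int = 0,
) -> ExpFit:
    """Least-squares fit of ``f(k) = B * m^k + D`` to ``C(k)``.

    The fit is parametrized directly in ``m`` (bounded in
    ``[exp(-10), 1.05]``) so near- and supercritical windows remain
    expressible; ``tau = -dt / log(m)`` is derived from the minimizer and
    the identity ``m_hat = exp(-dt / tau)`` holds by construction. The
    landscape is non-convex, so after the data-driven initial attempt the
    initials are jittered (up to ``max_restarts`` extra attempts, at
    least ``min_attempts`` total) and the lowest-sse converged fit wins.
    """
    lags = acf.lags.astype(np.float64)
    coeffs = acf.coefficients
    if lags.size < 4:
        raise InsufficientDataError("exponential-with-offset fit needs >= 4 lags")

    rng = np.random.default_rng(seed)
    base = _initial_guess(lags, coeffs)
    lower = np.array([B_BOUNDS[0], M_BOUNDS[0], D_BOUNDS[0]])
    upper = np.array([B_BOUNDS[1], M_BOUNDS[1], D_BOUNDS[1]])

    best: Optional[tuple[float, np.ndarray]] = None
    attempts = 0
    max_attempts = 1 + max_restarts
    while attempts < max_attempts:
        if attempts == 0:
            x0 = _clip_to_bounds(base)
        else:
            jitter = np.array(
                [
                    base[0] * rng.uniform(0.5, 1.5),
                    base[1] * rng.uniform(0.9, 1.0 / max(base[1], 0.9)),
                    base[2] + rng.normal(scale=0.05),
                ]
            )
            x0 = _clip_to_bounds(jitter)
        attempts += 1
        try:
            sol = least_squares(
                _residuals,
                x0,
                jac=_jacobian,
                bounds=(lower, upper),
                args=(lags, coeffs),
                method="trf",
            )
        except Exception:
            continue
        if not sol.success:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
        if attempts >= min_attempts and best is not None:
            break

    if best is None:
        raise FitFailureError(
            f"exponential fit did not converge after {attempts} attempts "
            f"(n_lags={lags.size}, C(1)={coeffs[0]:.4g})"
        )
    sse, (B, m, D) = best[0], best[1]
    if m == 1.0:
        tau = math.inf
    else:
        tau = -bin_size / math.log(m)
    return ExpFit(B=float(B), tau=float(tau), D=float(D), m_hat=float(m), sse=sse)


def fit_linear(acf: AcfEstimate) -> LinearFit:
    """OLS line through ``(k * dt, C(k))``; the exclusion benchmark."""
    if acf.lags.size < 2:
        raise InsufficientDataError("linear fit needs >= 2 lags")
    t = acf.lag_times
    slope, intercept = np.polyfit(t, acf.coefficients, 1)
    resid = acf.coefficients - (slope * t + intercept)
    return LinearFit(slope=float(slope), intercept=float(intercept), sse=float(np.sum(resid**2)))


# ---------------------------------------------------------------------------
# Consistency checks and orchestration
# ---------------------------------------------------------------------------

def _exp_beats_linear(exp_fit: ExpFit, lin_fit: LinearFit, n_lags: int, criterion: str) -> bool:
    if criterion == "aic":
        # Gaussian AIC: n log(sse/n) + 2p, with p = 3 vs 2 parameters.
        aic_exp = n_lags * math.log(max(exp_fit.sse, 1e-300) / n_lags) + 2 * 3
        aic_lin = n_lags * math.log(max(lin_fit.sse, 1e-300) / n_lags) + 2 * 2
        return aic_exp < aic_lin
    return exp_fit.sse < lin_fit.sse


def check_consistency(
    trace: ActivityTrace,
    acf: AcfEstimate,
    exp_fit: ExpFit,
    lin_fit: LinearFit,
    criterion: str = "aic",
) -> ConsistencyFlags:
    """Exclusion criteria: >= 1000 non-zero bins, and exponential decay
    fitting the ACF better than a straight line."""
    return ConsistencyFlags(
        enough_nonzero=trace.n_nonzero >= MIN_NONZERO_BINS,
        exp_beats_linear=_exp_beats_linear(exp_fit, lin_fit, acf.lags.size, criterion),
        supercritical=exp_fit.supercritical,
    )


def log_distance(m_hat: float) -> float:
    """Logarithmic distance to criticality ``epsilon = log(1 - m_hat)``."""
    if m_hat >= 1.0:
        raise ValueError(f"log distance undefined for m_hat >= 1 (got {m_hat})")
    return math.log(1.0 - m_hat)


def estimate_m(trace: ActivityTrace, config: EstimationConfig = EstimationConfig()) -> MrResult:
    """Full MR estimation on one activity trace.

    Orchestrates the autocorrelation, the exponential and linear fits,
    the consistency checks and (optionally) the block-bootstrap CI. An
    excluded trace is returned with ``accepted=False``, never dropped.
    """
    k_max = config.resolved_k_max(trace.bin_size)
    acf = compute_acf(trace, k_max)
    exp_fit = fit_exp_offset(
        acf,
        trace.bin_size,
        max_restarts=config.max_restarts,
        min_attempts=config.min_fit_attempts,
        seed=config.fit_seed,
    )
    lin_fit = fit_linear(acf)
    flags = check_consistency(trace, acf, exp_fit, lin_fit, config.linear_comparison)

    ci_low = ci_high = math.nan
    if config.n_boot > 0:
        try:
            ci_low, ci_high = bootstrap_ci(trace, config)
            flags = replace(flags, ci_available=True)
        except InsufficientDataError:
            pass

    epsilon = log_distance(exp_fit.m_hat) if exp_fit.m_hat < 1.0 else None
    return MrResult(
        fit=exp_fit,
        epsilon=epsilon,
        ci_low=ci_low,
        ci_high=ci_high,
        n_nonzero=trace.n_nonzero,
        flags=flags,
        accepted=flags.enough_nonzero and flags.exp_beats_linear,
    )


def naive_lag1_slope(trace: ActivityTrace) -> float:
    """Conventional lag-1 regression estimate of m (OLS slope of
    ``A_{t+1}`` on ``A_t``), which under subsampling is biased towards
    zero by the amplitude factor B."""
    return float(compute_acf(trace, 1).coefficients[0])


# ---------------------------------------------------------------------------
# Block bootstrap ("stationary mean" variant)
# ---------------------------------------------------------------------------

def bootstrap_ci(trace: ActivityTrace, config: EstimationConfig = EstimationConfig()) -> tuple[float, float]:
    """Percentile bootstrap CI on ``m_hat`` from 20 s blocks.

    The trace is cut into consecutive ``boot_block_seconds`` blocks; each
    replicate resamples blocks with replacement, recomputes the ACF with
    the pooled (stationary) mean of the selected blocks and per-block
    lagged cross-products, refits the exponential, and records its
    ``m_hat``. Seeded and reproducible.
    """
    block_bins = int(round(config.boot_block_seconds / trace.bin_size))
    A = trace.counts.astype(np.float64)
    n_blocks = A.size // block_bins
    if n_blocks < 2:
        raise InsufficientDataError(
            f"bootstrap needs >= 2 blocks of {config.boot_block_seconds} s "
            f"(trace spans {trace.duration:.1f} s)"
        )
    if config.n_boot < 1:
        raise InsufficientDataError("n_boot must be >= 1")

    k_max = config.resolved_k_max(trace.bin_size)
    if k_max >= block_bins:
        raise InsufficientDataError("block shorter than the lag range")
    blocks = A[: n_blocks * block_bins].reshape(n_blocks, block_bins)
    lags = np.arange(1, k_max + 1)

    # Per-block, per-lag sufficient statistics so each replicate's ACF is a
    # cheap linear combination (pooled mean handled via expansion of the
    # demeaned products).
    S_xy = np.empty((n_blocks, k_max))
    S_x = np.empty((n_blocks, k_max))
    S_y = np.empty((n_blocks, k_max))
    S_xx = np.empty((n_blocks, k_max))
    for i, k in enumerate(lags):
        x = blocks[:, : block_bins - k]
        y = blocks[:, k:]
        S_xy[:, i] = np.einsum("bi,bi->b", x, y)
        S_x[:, i] = x.sum(axis=1)
        S_y[:, i] = y.sum(axis=1)
        S_xx[:, i] = np.einsum("bi,bi->b", x, x)
    n_pairs = (block_bins - lags).astype(np.float64)
    block_sums = blocks.sum(axis=1)

    rng = np.random.default_rng(config.boot_seed)
    m_reps = []
    for _ in range(config.n_boot):
        idx = rng.integers(0, n_blocks, size=n_blocks)
        mu = block_sums[idx].sum() / (n_blocks * block_bins)
        num = S_xy[idx].sum(axis=0) - mu * (S_x[idx] + S_y[idx]).sum(axis=0) + n_blocks * n_pairs * mu**2
        den = S_xx[idx].sum(axis=0) - 2.0 * mu * S_x[idx].sum(axis=0) + n_blocks * n_pairs * mu**2
        if np.any(den <= 0):
            continue
        acf = AcfEstimate(lags=lags, coefficients=num / den, n_used=n_pairs * n_blocks,
                          bin_size=trace.bin_size)
        try:
            fit = fit_exp_offset(
                acf,
                trace.bin_size,
                max_restarts=config.max_restarts,
                min_attempts=1,
                seed=config.fit_seed,
            )
        except FitFailureError:
            continue
        m_reps.append(fit.m_hat)

    if not m_reps:
        raise InsufficientDataError("all bootstrap replicates failed")
    lo_q = (1.0 - config.ci_level) / 2.0
    lo, hi = np.quantile(m_reps, [lo_q, 1.0 - lo_q])
    return float(lo), float(hi)
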