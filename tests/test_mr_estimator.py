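"""MR estimator: ACF oracle equivalence, exact fit recovery, the
definitional identity m = exp(-dt/tau), exclusion rules, and the block
bootstrap contract."""

import math

import numpy as np
import pytest

from mrcrit import (
    ActivityTrace,
    EstimationConfig,
    bootstrap_ci,
    check_consistency,
    compute_acf,
    estimate_m,
    fit_exp_offset,
    fit_linear,
    log_distance,
    naive_lag1_slope,
    simulate_stationary,
    subsample_trace,
    SubsampleSpec,
)
from mrcrit.mr_estimator import (
    AcfEstimate,
    InsufficientDataError,
    MIN_NONZERO_BINS,
    ZeroVarianceError,
    default_k_max,
)

from conftest import FAST_EST


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Brute-force OLS slope of y on x — the lag-k regression oracle."""
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


class TestComputeAcf:
    def test_period_two_alternation_has_unit_lag2_correlation(self):
        trace = ActivityTrace(np.array([1, 2, 1, 2, 1, 2]))
        acf = compute_acf(trace, 2)
        assert acf.coefficients[1] == pytest.approx(1.0)

    def test_constant_trace_raises_zero_variance(self):
        with pytest.raises(ZeroVarianceError):
            compute_acf(ActivityTrace(np.full(100, 7)), 5)

    def test_k_max_must_be_shorter_than_trace(self):
        trace = ActivityTrace(np.arange(10))
        with pytest.raises(ValueError):
            compute_acf(trace, 10)

    def test_matches_lag_k_ols_slope_oracle(self, stationary_trace_m09):
        # Eq-style ACF with segment means == OLS slope of A_{t+k} on A_t
        A = stationary_trace_m09.counts.astype(float)[:2000]
        acf = compute_acf(ActivityTrace(A.astype(int)), 50)
        for i, k in enumerate(acf.lags):
            oracle = _ols_slope(A[:-k], A[k:])
            assert abs(acf.coefficients[i] - oracle) <= 1e-10 * max(1.0, abs(oracle))

    def test_branching_run_acf_decays_geometrically(self, stationary_trace_m09):
        acf = compute_acf(stationary_trace_m09, 5)
        for i, k in enumerate(acf.lags):
            assert acf.coefficients[i] == pytest.approx(0.9**k, abs=0.05)

    def test_default_lag_range_is_1600_ms(self):
        assert default_k_max(0.004) == 400
        assert default_k_max(0.002) == 800


class TestFitExpOffset:
    def _acf(self, B, m, D, k_max=100, bin_size=0.004):
        k = np.arange(1, k_max + 1)
        return AcfEstimate(lags=k, coefficients=B * m**k + D,
                           n_used=np.full(k_max, 1000), bin_size=bin_size)

    def test_noiseless_model_recovered_exactly(self):
        fit = fit_exp_offset(self._acf(0.5, 0.9, 0.01), 0.004)
        assert fit.B == pytest.approx(0.5, abs=1e-6)
        assert fit.m_hat == pytest.approx(0.9, abs=1e-6)
        assert fit.D == pytest.approx(0.01, abs=1e-6)

    @pytest.mark.parametrize("B,m,D", [(1.0, 0.95, 0.0), (0.05, 0.99, -0.002), (2.0, 0.5, 0.1)])
    def test_identity_m_equals_exp_of_tau(self, B, m, D):
        fit = fit_exp_offset(self._acf(B, m, D), 0.004)
        assert fit.m_hat == pytest.approx(math.exp(-0.004 / fit.tau), rel=1e-12)

    def test_supercritical_acf_yields_flagged_fit(self):
        # growing "autocorrelation" -> m > 1, negative-tau branch
        k = np.arange(1, 40)
        acf = AcfEstimate(lags=k, coefficients=0.01 * 1.02**k,
                          n_used=np.full(38, 1000), bin_size=0.004)
        fit = fit_exp_offset(acf, 0.004)
        assert fit.supercritical
        assert fit.m_hat == pytest.approx(1.02, abs=0.005)
        assert fit.tau < 0
        assert fit.m_hat == pytest.approx(math.exp(-0.004 / fit.tau), rel=1e-12)

    def test_too_few_lags_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_exp_offset(self._acf(0.5, 0.9, 0.0, k_max=3), 0.004)


class TestFitLinear:
    def test_exact_line_has_zero_sse(self):
        k = np.arange(1, 20)
        acf = AcfEstimate(lags=k, coefficients=0.5 - 0.01 * k,
                          n_used=np.full(19, 100), bin_size=0.004)
        fit = fit_linear(acf)
        assert fit.sse == pytest.approx(0.0, abs=1e-20)

    def test_exponential_beats_line_on_exact_exponential(self):
        k = np.arange(1, 101)
        acf = AcfEstimate(lags=k, coefficients=0.5 * 0.9**k,
                          n_used=np.full(100, 100), bin_size=0.004)
        exp_fit = fit_exp_offset(acf, 0.004)
        lin_fit = fit_linear(acf)
        assert exp_fit.sse < lin_fit.sse

    def test_single_lag_rejected(self):
        acf = AcfEstimate(lags=np.array([1]), coefficients=np.array([0.5]),
                          n_used=np.array([10]), bin_size=0.004)
        with pytest.raises(InsufficientDataError):
            fit_linear(acf)


class TestConsistencyChecks:
    def _trace_with_nonzero(self, n_nonzero, total=5000):
        rng = np.random.default_rng(3)
        counts = np.zeros(total, dtype=int)
        idx = rng.choice(total, size=n_nonzero, replace=False)
        counts[idx] = rng.poisson(2.0, size=n_nonzero) + 1
        return ActivityTrace(counts)

    @pytest.mark.parametrize("n_nonzero,expected", [(999, False), (1000, True), (1001, True)])
    def test_nonzero_bin_threshold_is_inclusive(self, n_nonzero, expected):
        trace = self._trace_with_nonzero(n_nonzero)
        acf = compute_acf(trace, 20)
        exp_fit = fit_exp_offset(acf, trace.bin_size)
        lin_fit = fit_linear(acf)
        flags = check_consistency(trace, acf, exp_fit, lin_fit)
        assert flags.enough_nonzero is expected

    def test_white_noise_frequently_fails_exp_vs_linear(self, noise_trace):
        # iid counts have a flat ACF; over many noise traces the
        # exponential should usually not beat the line
        rng = np.random.default_rng(17)
        fails = 0
        n = 20
        for _ in range(n):
            tr = ActivityTrace(rng.poisson(0.5, size=15000))
            acf = compute_acf(tr, 100)
            flags = check_consistency(tr, acf, fit_exp_offset(acf, tr.bin_size), fit_linear(acf))
            fails += not flags.exp_beats_linear
        assert fails > n / 2

    def test_branching_trace_passes_both_checks(self, stationary_trace_m09):
        res = estimate_m(stationary_trace_m09, FAST_EST)
        assert res.accepted
        assert res.flags.enough_nonzero and res.flags.exp_beats_linear

    def test_shortening_never_flips_enough_nonzero_to_true(self, stationary_trace_m09):
        # exclusion monotonicity: prefixes have no more non-zero bins
        counts = stationary_trace_m09.counts
        nz = np.cumsum(counts != 0)
        assert np.all(np.diff(nz) >= 0)
        full_nz = nz[-1]
        for cut in (len(counts) // 2, len(counts) // 4):
            assert nz[cut - 1] <= full_nz


class TestEstimateM:
    def test_recovers_generating_m_subsampled(self, stationary_trace_m095):
        sub = subsample_trace(stationary_trace_m095, SubsampleSpec(0.01, seed=4))
        res = estimate_m(sub, EstimationConfig(n_boot=0))
        assert res.accepted
        assert res.m_hat == pytest.approx(0.95, abs=0.02)
        assert res.epsilon == pytest.approx(math.log(1 - res.m_hat))

    def test_all_zero_trace_raises(self):
        with pytest.raises(ZeroVarianceError):
            estimate_m(ActivityTrace(np.zeros(5000, dtype=int)), FAST_EST)

    def test_naive_lag1_slope_is_biased_under_subsampling(self, stationary_trace_m095):
        sub = subsample_trace(stationary_trace_m095, SubsampleSpec(0.01, seed=4))
        naive = naive_lag1_slope(sub)
        multistep = estimate_m(sub, EstimationConfig(n_boot=0)).m_hat
        assert naive < 0.5 < multistep  # amplitude bias B ~ alpha kills lag-1

    def test_excluded_trace_returned_not_dropped(self):
        rng = np.random.default_rng(8)
        counts = np.zeros(6000, dtype=int)
        idx = rng.choice(6000, size=500, replace=False)  # < 1000 non-zero
        counts[idx] = 1
        res = estimate_m(ActivityTrace(counts), EstimationConfig(k_max_bins=50, n_boot=0))
        assert not res.accepted
        assert not res.flags.enough_nonzero
        assert res.n_nonzero == 500


class TestBootstrapCi:
    def test_identical_seed_gives_identical_ci(self, stationary_trace_m09):
        cfg = EstimationConfig(k_max_bins=150, n_boot=30, boot_seed=5)
        assert bootstrap_ci(stationary_trace_m09, cfg) == bootstrap_ci(stationary_trace_m09, cfg)

    def test_single_replicate_is_degenerate(self, stationary_trace_m09):
        lo, hi = bootstrap_ci(stationary_trace_m09, EstimationConfig(k_max_bins=150, n_boot=1))
        assert lo == hi

    def test_short_trace_flagged_unavailable(self):
        trace = simulate_stationary(0.8, 1.0, 7000, seed=6)  # 28 s < 2 blocks
        with pytest.raises(InsufficientDataError):
            bootstrap_ci(trace, EstimationConfig(k_max_bins=100, n_boot=10))
        res = estimate_m(trace, EstimationConfig(k_max_bins=100, n_boot=10))
        assert not res.flags.ci_available
        assert math.isnan(res.ci_low) and math.isnan(res.ci_high)

    def test_ci_brackets_generating_m(self, stationary_trace_m095):
        cfg = EstimationConfig(n_boot=100, boot_seed=2)
        lo, hi = bootstrap_ci(stationary_trace_m095, cfg)
        assert lo < 0.95 < hi
        assert hi - lo < 0.05


class TestLogDistance:
    def test_analytic_values(self):
        assert log_distance(0.0) == pytest.approx(0.0)
        assert log_distance(0.9) == pytest.approx(math.log(0.1))

    @pytest.mark.parametrize("m", [1.0, 1.01])
    def test_critical_and_beyond_rejected(self, m):
        with pytest.raises(ValueError):
            log_distance(m)
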