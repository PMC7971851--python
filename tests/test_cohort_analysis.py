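"""Cohort statistics: split-half convention, exact signed-rank null,
MAD, mixed-model recovery, Bonferroni gating, and the full-cohort
orchestration on a small synthetic cohort."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mrcrit import (
    ActivityTrace,
    CohortConfig,
    EstimationConfig,
    WindowConfig,
    bonferroni_gate,
    fit_group_model,
    mad_of_series,
    mann_whitney_contrast,
    paired_signed_rank,
    run_cohort,
    split_halves,
)
from mrcrit.mr_estimator import InsufficientDataError


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Independent oracle: two-sided signed-rank p by enumerating all
    2^n sign assignments of the ranked |differences| (zeros dropped)."""
    d = diffs[diffs != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= w_obs:
            count += 1
    return count / 2**n


class TestSplitHalves:
    def test_even_600s_epoch_splits_into_75000_bin_halves(self):
        trace = ActivityTrace(np.ones(150000, dtype=int))
        first, second = split_halves(trace)
        assert len(first) == len(second) == 75000
        assert second.start_time == pytest.approx(300.0)

    def test_odd_count_first_half_gets_extra_bin(self):
        trace = ActivityTrace(np.arange(601) % 3)
        first, second = split_halves(trace)
        assert len(first) == 301 and len(second) == 300

    def test_spike_counts_conserved_across_split(self):
        rng = np.random.default_rng(4)
        trace = ActivityTrace(rng.poisson(1.0, size=1001))
        first, second = split_halves(trace)
        assert first.counts.sum() + second.counts.sum() == trace.counts.sum()


class TestPairedSignedRank:
    def test_identical_lists_give_p_one(self):
        res = paired_signed_rank([-2.0, -2.5, -3.0], [-2.0, -2.5, -3.0])
        assert res.p_value == 1.0
        assert res.effect == 0.0

    def test_six_one_sided_pairs_exact_p(self):
        a = np.full(6, -2.5)
        b = a + 0.3
        res = paired_signed_rank(a, b)
        assert res.p_value == pytest.approx(2 / 2**6)
        assert res.effect == pytest.approx(0.3)

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            a = rng.normal(-2.5, 0.4, size=n)
            b = a + rng.normal(0.1, 0.3, size=n)
            res = paired_signed_rank(a, b)
            assert res.p_value == pytest.approx(exact_signed_rank_p(b - a), abs=1e-12)

    def test_pairs_with_undefined_epsilon_dropped_and_counted(self):
        a = [-2.0, None, -2.2, math.nan, -2.4]
        b = [-2.1, -2.0, -2.3, -2.0, -2.5]
        res = paired_signed_rank(a, b)
        assert res.n == 3
        assert res.n_dropped == 2

    def test_fewer_than_two_usable_pairs_errors(self):
        with pytest.raises(InsufficientDataError):
            paired_signed_rank([-2.0, None], [-2.1, -2.2])

    def test_null_rejection_rate_near_nominal(self):
        # exchangeable pairs: exact test rejects at ~alpha
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            rejections += paired_signed_rank(a, b).p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


class TestMad:
    def test_constant_series_zero(self):
        assert mad_of_series([-2.0] * 5) == 0.0

    def test_hand_arithmetic(self):
        assert mad_of_series([-2.0, -2.3, -2.6]) == pytest.approx(0.3)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=31)
        assert mad_of_series(x + 1.7) == pytest.approx(mad_of_series(x))

    def test_nan_entries_ignored_and_all_nan_errors(self):
        assert mad_of_series([-2.0, math.nan, -2.6]) == pytest.approx(0.3)
        with pytest.raises(InsufficientDataError):
            mad_of_series([math.nan, None])


class TestGroupModel:
    def _table(self, focus_shift, n_patients=8, n_rec=4, sd_patient=0.3, sd_noise=0.2, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_patients):
            intercept = -3.0 + rng.normal(scale=sd_patient)
            for r in range(n_rec):
                for focus, shift in (("contralateral", 0.0), ("ipsilateral", focus_shift)):
                    rows.append(dict(
                        patient_id=f"P{p}", focus=focus,
                        epsilon=intercept + shift + rng.normal(scale=sd_noise),
                    ))
        return pd.DataFrame(rows)

    def test_zero_effect_estimated_near_zero(self):
        res = fit_group_model(self._table(0.0, seed=1), "epsilon ~ focus", term="focus")
        assert abs(res.effect) < 0.15
        assert res.p_value > 0.01

    def test_known_shift_recovered(self):
        res = fit_group_model(self._table(-0.5, seed=2), "epsilon ~ focus", term="focus")
        assert res.effect == pytest.approx(-0.5, abs=0.15)
        assert res.p_value < 1e-4

    def test_single_patient_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            fit_group_model(self._table(-0.5, n_patients=1), "epsilon ~ focus")

    def test_null_rejection_rate_near_nominal(self):
        rejections = 0
        n_rep = 200
        for s in range(n_rep):
            res = fit_group_model(self._table(0.0, n_patients=6, n_rec=2, seed=1000 + s),
                                  "epsilon ~ focus", term="focus")
            rejections += res.p_value < 0.05
        assert 0.01 <= rejections / n_rep <= 0.11


class TestBonferroni:
    def test_fixed_divisor_four(self):
        decisions = bonferroni_gate({"H": 0.012, "A": 0.013, "PHC": 0.2, "EC": 0.0124})
        assert decisions == {"H": True, "A": False, "PHC": False, "EC": True}

    def test_number_of_tests_bounded(self):
        with pytest.raises(ValueError):
            bonferroni_gate({f"s{i}": 0.01 for i in range(5)})


class TestMannWhitney:
    def test_shifted_samples_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(-3.0, 0.1, size=12)
        b = rng.normal(-2.0, 0.1, size=12)
        res = mann_whitney_contrast(a, b)
        assert res.p_value < 1e-3
        assert res.effect == pytest.approx(1.0, abs=0.2)


class TestRunCohort:
    def test_full_pipeline_on_small_null_cohort(self, small_cohort):
        spec, records, manifest = small_cohort
        config = CohortConfig(
            est_config=EstimationConfig(k_max_bins=150, n_boot=0),
            window_config=WindowConfig(40.0, 10.0),
        )
        res = run_cohort(manifest, config, records=records)
        # every recording x hemisphere has an MTL row plus 4 subregion rows
        n_rec = spec.n_patients * spec.recordings_per_patient * 2
        assert len(res.estimates) == n_rec * 5
        assert res.hemispheric is not None
        assert res.hemispheric.p_value > 0.001  # no programmed effect
        assert set(res.split_half) <= {"ipsilateral", "contralateral"}
        assert res.n_supercritical >= 0

    def test_engel_subset_restricts_patients(self, small_cohort):
        spec, records, manifest = small_cohort
        config = CohortConfig(
            subset="engel1a",
            est_config=EstimationConfig(k_max_bins=150, n_boot=0),
            include_timeresolved=False, include_subregions=False,
        )
        res = run_cohort(manifest, config, records=records)
        engel_pids = {p["patient_id"] for p in manifest["patients"] if p["engel"] == "1a"}
        assert set(res.estimates["patient_id"]) == engel_pids

    def test_cohort_roundtrip_through_spike_tsv(self, small_cohort, tmp_path):
        from mrcrit import generate_cohort
        from conftest import reduced_cohort_spec

        spec = reduced_cohort_spec(n_patients=2, recordings_per_patient=1, duration=60.0)
        generate_cohort(spec, out_dir=tmp_path)
        config = CohortConfig(
            est_config=EstimationConfig(k_max_bins=100, n_boot=0),
            include_timeresolved=False, include_subregions=False,
        )
        res = run_cohort(tmp_path / "manifest.yaml", config)
        assert len(res.estimates) == 4  # 2 patients x 1 recording x 2 hemispheres
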