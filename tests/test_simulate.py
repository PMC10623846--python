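"""Dilution-model cohort generator: determinism, degenerate limits, the
analytic noise-free positivity rate, and the false-negative gradient."""

import numpy as np
import pandas as pd
import pytest

from vafqc import (
    SimConfig,
    expected_observed_score,
    make_hinge_curve,
    make_step_cohort,
    simulate_cohort,
)
from vafqc.cohort import Call, Subtype
from vafqc.simulate import analytic_positivity_noise_free


class TestExpectedObservedScore:
    @pytest.mark.parametrize(
        "f, s_tumor, s_bg, expected",
        [(1.0, 30.0, 2.0, 30.0), (0.0, 30.0, 2.0, 2.0), (0.5, 30.0, 2.0, 16.0)],
    )
    def test_mixture_endpoints_and_midpoint(self, f, s_tumor, s_bg, expected):
        assert expected_observed_score(f, s_tumor, s_bg) == pytest.approx(expected)

    @pytest.mark.parametrize("f", [-0.1, 1.1])
    def test_fraction_domain(self, f):
        with pytest.raises(ValueError):
            expected_observed_score(f, 30.0, 2.0)

    def test_signal_domain(self):
        with pytest.raises(ValueError):
            expected_observed_score(0.5, 130.0, 2.0)


class TestSimulateCohort:
    def test_same_seed_bit_identical(self):
        a, _ = simulate_cohort(SimConfig(n=100, seed=5))
        b, _ = simulate_cohort(SimConfig(n=100, seed=5))
        assert a == b
        c, _ = simulate_cohort(SimConfig(n=100, seed=6))
        assert a != c

    def test_pure_methylated_noise_free_limit(self):
        # prevalence 1, all sigmas 0, VAF pinned at ~0.5: every sample is a
        # pure tumor scoring mu_meth, so positivity is exactly 1
        cfg = SimConfig(
            n=50,
            prevalence_by_subtype={st: 1.0 for st in Subtype},
            vaf_beta_params={st: (5e5, 1e-3) for st in Subtype},
            sigma_signal=0.0,
            sigma_noise=0.0,
            micro_sigma=0.0,
            seed=2,
        )
        cohort, truth = simulate_cohort(cfg)
        scores = np.array([s.mgmt_score for s in cohort])
        assert np.allclose(scores, 30.0, atol=0.01)
        assert all(s.mgmt_call is Call.POSITIVE for s in cohort)

    def test_unmethylated_cohort_all_negative(self):
        cfg = SimConfig(
            n=50,
            prevalence_by_subtype={st: 0.0 for st in Subtype},
            sigma_signal=0.5,
            sigma_noise=0.5,
            seed=3,
        )
        cohort, truth = simulate_cohort(cfg)
        assert all(s.mgmt_call is Call.NEGATIVE for s in cohort)
        assert not truth["true_methylated"].any()

    def test_truth_tumor_fraction_invariant(self):
        cohort, truth = simulate_cohort(SimConfig(n=200, seed=4))
        vaf = np.array([s.driver_vaf for s in cohort])
        assert np.allclose(truth["tumor_fraction"], np.minimum(2 * vaf, 1.0))

    def test_low_vaf_false_negatives_exceed_high_vaf(self):
        # majority rule over seeds: truly methylated samples below VAF 0.10
        # miss the cutoff more often than those above VAF 0.40
        wins = 0
        for seed in range(5):
            cohort, truth = simulate_cohort(SimConfig(n=2000, seed=seed))
            df = cohort.to_dataframe().merge(truth, on="sample_id")
            meth = df[df["true_methylated"]]
            fn_low = meth[meth["driver_vaf"] < 0.10]["mgmt_call"].eq("NEGATIVE").mean()
            fn_high = meth[meth["driver_vaf"] > 0.40]["mgmt_call"].eq("NEGATIVE").mean()
            wins += fn_low > fn_high
        assert wins >= 3

    def test_microscopy_bias_positive_at_low_purity(self):
        cohort, truth = simulate_cohort(SimConfig(n=2000, seed=8))
        df = cohort.to_dataframe().merge(truth, on="sample_id")
        low = df[df["tumor_fraction"] < 0.4]
        bias = (low["micro_cellularity"] - 100 * low["tumor_fraction"]).mean()
        assert bias > 0

    def test_noise_free_positivity_matches_analytic_value(self):
        cfg = SimConfig(
            n=5000, sigma_signal=0.0, sigma_noise=0.0, micro_sigma=0.0, seed=9
        )
        cohort, _ = simulate_cohort(cfg)
        emp = np.mean([s.mgmt_call is Call.POSITIVE for s in cohort])
        expected = analytic_positivity_noise_free(cfg)
        se = np.sqrt(expected * (1 - expected) / cfg.n)
        assert abs(emp - expected) <= 3 * se

    @pytest.mark.parametrize(
        "bad",
        [
            {"n": 0},
            {"sigma_noise": -1.0},
            {"mu_background": 15.0},  # violates background < cutoff < meth
            {"subtype_mix": {st: 0.5 for st in Subtype}},  # sums to 1.5
        ],
    )
    def test_invalid_config_rejected_before_sampling(self, bad):
        with pytest.raises(ValueError):
            simulate_cohort(SimConfig(**bad))


class TestHelpers:
    def test_hinge_exactness_and_determinism(self):
        curve = make_hinge_curve(0.2, 1.0, 0.2, grid_step=0.02, noise_sd=0.0)
        x = curve.vaf_ranked
        expected = np.where(x <= 0.2, x, 0.2)
        assert np.allclose(curve.cumulative_value, expected)
        a = make_hinge_curve(0.2, 1.0, 0.2, noise_sd=0.05, seed=13)
        b = make_hinge_curve(0.2, 1.0, 0.2, noise_sd=0.05, seed=13)
        assert np.array_equal(a.cumulative_value, b.cumulative_value)

    def test_flat_hinge(self):
        curve = make_hinge_curve(0.2, 0.0, 0.3, noise_sd=0.0)
        assert np.allclose(curve.cumulative_value, 0.3)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_hinge_curve(0.7, 1.0, 0.2)
        with pytest.raises(ValueError):
            make_hinge_curve(0.2, 1.0, 0.2, grid_step=0.0)

    def test_step_cohort_structure(self):
        cohort = make_step_cohort(n=300, step_vaf=0.2, seed=21)
        assert len(cohort) == 300
        df = cohort.to_dataframe()
        pos_high = df[df["driver_vaf"] >= 0.2]["mgmt_call"].eq("POSITIVE").mean()
        pos_low = df[df["driver_vaf"] < 0.2]["mgmt_call"].eq("POSITIVE").mean()
        assert pos_high > pos_low
        assert cohort == make_step_cohort(n=300, step_vaf=0.2, seed=21)
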