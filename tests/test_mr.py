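"""Estimator oracles and invariances for the two-sample MR methods."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_hset
from targetmr import mr


class TestWaldRatio:
    def test_ratio_and_delta_se(self):
        est = mr.wald_ratio(0.1, 0.02, 0.2, 0.05)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_null_outcome_gives_p_one(self):
        est = mr.wald_ratio(0.1, 0.02, 0.0, 0.05)
        assert est.beta == 0.0 and est.pval == pytest.approx(1.0)

    def test_null_instrument_rejected(self):
        with pytest.raises(ValueError, match="null instrument"):
            mr.wald_ratio(0.0, 0.02, 0.2, 0.05)

    def test_or_scale_is_exp_of_beta_scale(self):
        est = mr.wald_ratio(0.1, 0.02, 0.2, 0.05, binary=True)
        assert est.or_scale == pytest.approx(
            (np.exp(est.beta), np.exp(est.ci_low), np.exp(est.ci_high)))


class TestIVW:
    def test_two_instrument_closed_form(self, two_instrument_set):
        """Weights 1 and 4 on ratios 2.0 and 1.5 give 1.6 exactly."""
        est = mr.ivw(two_instrument_set, mode="fixed")
        assert est.beta == pytest.approx(1.6, abs=1e-12)
        assert est.se == pytest.approx((0.1**2 / 0.01 + 0.2**2 / 0.01) ** -0.5)

    def test_single_instrument_reduces_to_wald(self):
        hs = make_hset([0.13], [0.02], [0.21], [0.06])
        est = mr.ivw(hs)
        wald = mr.wald_ratio(0.13, 0.02, 0.21, 0.06)
        assert est.beta == pytest.approx(wald.beta, abs=1e-15)
        assert est.se == pytest.approx(wald.se, abs=1e-15)

    def test_identical_ratios_give_zero_q_and_equal_ses(self):
        hs = make_hset([0.1, 0.2, 0.3], [0.01], [0.15, 0.3, 0.45], [0.05])
        fixed = mr.ivw(hs, mode="fixed")
        random = mr.ivw(hs, mode="multiplicative_random")
        assert fixed.beta == pytest.approx(1.5)
        assert mr.cochran_q(hs).q == pytest.approx(0.0, abs=1e-20)
        assert random.se == pytest.approx(fixed.se)

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=25, deadline=None)
    def test_permutation_and_sign_flip_invariance(self, rnd):
        rng = np.random.default_rng(rnd.randrange(2**31))
        n = 8
        bx = rng.normal(0.1, 0.03, n)
        by = rng.normal(0.05, 0.02, n)
        sy = rng.uniform(0.01, 0.05, n)
        base = mr.ivw(make_hset(bx, 0.01, by, sy), mode="fixed").beta
        perm = rng.permutation(n)
        assert mr.ivw(make_hset(bx[perm], 0.01, by[perm], sy[perm]),
                      mode="fixed").beta == pytest.approx(base)
        flip = rng.choice([-1.0, 1.0], n)
        assert mr.ivw(make_hset(bx * flip, 0.01, by * flip, sy),
                      mode="fixed").beta == pytest.approx(base)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mr.ivw(make_hset([], [], [], []))


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        hs = make_hset(bx, 0.01, 1.7 * bx, [0.05, 0.04, 0.05, 0.06])
        slope, intercept = mr.mr_egger(hs)
        assert slope.beta == pytest.approx(1.7, abs=1e-10)
        assert intercept.beta == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_recovered_as_intercept(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3, 0.4])
        hs = make_hset(bx, 0.01, 1.7 * bx + 0.05, 0.05)
        slope, intercept = mr.mr_egger(hs)
        assert intercept.beta == pytest.approx(0.05, abs=1e-10)
        assert slope.beta == pytest.approx(1.7, abs=1e-10)

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.05, 0.3, 12)
        sy = rng.uniform(0.02, 0.08, 12)
        by = 0.8 * bx + 0.02 + rng.normal(0, sy)
        fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2).fit()
        slope, intercept = mr.mr_egger(make_hset(bx, 0.01, by, sy))
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-12)
        assert intercept.beta == pytest.approx(fit.params[0], abs=1e-12)
        scale_floor = np.sqrt(max(1.0, fit.scale) / fit.scale)
        assert slope.se == pytest.approx(fit.bse[1] * scale_floor, rel=1e-9)

    def test_requires_three_instruments(self, two_instrument_set):
        with pytest.raises(ValueError):
            mr.mr_egger(two_instrument_set)


class TestWeightedMedian:
    def test_median_robust_to_single_outlier(self):
        # equal ratio variances -> equal weights; ratios {1, 2, 100}
        hs = make_hset([1.0, 1.0, 1.0], 1e-9, [1.0, 2.0, 100.0], 1.0)
        est = mr.weighted_median(hs, n_boot=100, seed=0)
        assert est.beta == pytest.approx(2.0, abs=1e-6)

    def test_dominant_weight_instrument_wins(self):
        # first instrument carries >50% of total weight -> its ratio
        hs = make_hset([1.0, 0.05, 0.05], 0.001, [3.0, 0.01, 0.02],
                       [0.05, 0.5, 0.5])
        est = mr.weighted_median(hs, n_boot=100, seed=0)
        assert est.beta == pytest.approx(3.0, abs=0.05)

    def test_equal_weights_match_unweighted_median(self):
        rng = np.random.default_rng(3)
        ratios = rng.normal(1.0, 0.3, 7)
        hs = make_hset(np.ones(7), 1e-6, ratios, 1.0)
        est = mr.weighted_median(hs, n_boot=10, seed=0)
        assert est.beta == pytest.approx(np.median(ratios), abs=1e-6)

    def test_bootstrap_reproducible(self):
        hs = make_hset([0.1, 0.12, 0.2, 0.25], 0.01,
                       [0.15, 0.2, 0.31, 0.4], 0.05)
        a = mr.weighted_median(hs, n_boot=200, seed=11)
        b = mr.weighted_median(hs, n_boot=200, seed=11)
        assert a.se == b.se and a.beta == b.beta


class TestModeEstimate:
    def test_dominant_cluster(self):
        hs = make_hset(np.ones(4), 0.001, [2.0, 2.01, 1.99, 5.0], 0.1)
        est = mr.mode_estimate(hs, kind="simple", n_boot=50, seed=0)
        assert est.beta == pytest.approx(2.0, abs=0.1)

    def test_degenerate_identical_ratios(self):
        hs = make_hset([0.1, 0.2, 0.4], 0.01, [0.15, 0.3, 0.6], 0.05)
        est = mr.mode_estimate(hs, kind="weighted", n_boot=50, seed=0)
        assert est.beta == pytest.approx(1.5, abs=1e-9)

    def test_two_clusters_majority_wins_on_grid(self):
        ratios = np.array([1.0, 0.98, 1.02, 0.99, 1.01, 1.0, 3.0, 2.98, 3.02])
        hs = make_hset(np.ones(9), 0.001, ratios, 0.1)
        est = mr.mode_estimate(hs, kind="simple", n_boot=50, seed=0)
        # independent density oracle on the same grid
        sd = np.std(ratios, ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.349) * 9 ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
        dens = np.sum(np.exp(-0.5 * ((grid[:, None] - ratios) / h) ** 2), axis=1)
        assert est.beta == pytest.approx(grid[np.argmax(dens)], abs=1e-12)
        assert abs(est.beta - 1.0) < 0.2


class TestCochranQ:
    def test_worked_example(self, two_instrument_set):
        rep = mr.cochran_q(two_instrument_set)
        assert rep.q == pytest.approx(0.2, abs=1e-12)
        assert rep.df == 1
        assert rep.pval == pytest.approx(stats.chi2.sf(0.2, 1))

    def test_permutation_invariant_and_zero_iff_equal(self):
        hs = make_hset([0.1, 0.2, 0.3], 0.01, [0.12, 0.26, 0.3], 0.05)
        q1 = mr.cochran_q(hs).q
        perm = make_hset([0.3, 0.1, 0.2], 0.01, [0.3, 0.12, 0.26], 0.05)
        assert mr.cochran_q(perm).q == pytest.approx(q1)
        assert q1 > 0

    def test_single_instrument_rejected(self):
        with pytest.raises(ValueError):
            mr.cochran_q(make_hset([0.1], [0.01], [0.2], [0.05]))


class TestMRPRESSO:
    def test_requires_four_instruments(self):
        hs = make_hset([0.1, 0.2, 0.3], 0.01, [0.1, 0.2, 0.3], 0.05)
        with pytest.raises(ValueError, match="insufficient instruments"):
            mr.mr_presso(hs, n_sim=10, seed=0)

    def test_displaced_instrument_flagged(self):
        rng = np.random.default_rng(5)
        n = 10
        bx = rng.uniform(0.1, 0.3, n)
        sy = np.full(n, 0.02)
        by = 0.5 * bx + rng.normal(0, sy)
        by[4] += 10 * sy[4]
        hs = make_hset(bx, 0.005, by, sy)
        global_p, outliers = mr.mr_presso(hs, n_sim=500, seed=1)
        assert global_p < 0.05
        assert "rs5" in outliers

    def test_clean_data_not_flagged(self):
        rng = np.random.default_rng(6)
        n = 10
        bx = rng.uniform(0.1, 0.3, n)
        sy = np.full(n, 0.02)
        by = 0.5 * bx + rng.normal(0, sy)
        global_p, outliers = mr.mr_presso(make_hset(bx, 0.005, by, sy),
                                          n_sim=500, seed=2)
        assert global_p > 0.05 and outliers == []


class TestSuite:
    def test_single_instrument_degrades_to_wald(self):
        hs = make_hset([0.1], [0.01], [0.2], [0.05])
        suite = mr.run_mr_suite(hs)
        assert set(suite["estimates"]) == {"wald"}
        assert suite["heterogeneity"] is None

    def test_full_suite_concordant_on_causal_data(self):
        rng = np.random.default_rng(8)
        n = 15
        bx = rng.uniform(0.05, 0.2, n)
        sy = np.full(n, 0.01)
        by = 0.6 * bx + rng.normal(0, sy)
        suite = mr.run_mr_suite(make_hset(bx, 0.002, by, sy),
                                n_boot=100, n_presso=100)
        assert suite["direction_concordant"] is True
        expected = {"ivw", "egger_slope", "weighted_median", "simple_mode",
                    "weighted_mode"}
        assert expected <= set(suite["estimates"])
        assert suite["heterogeneity"].presso_global_p is not None
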