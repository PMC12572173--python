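"""Estimator arithmetic against independent closed-form oracles, plus
the sensitivity battery's behavioural contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabomr import (bidirectional, cochran_q, egger, ivw, leave_one_out,
                      max_likelihood, median_estimator, mode_estimator,
                      run_mr_suite, wald_ratio)
from tests.conftest import make_harmonised


def random_harmonised(rng, n, outcome_type="quantitative"):
    bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    sx = rng.uniform(0.005, 0.02, n)
    by = rng.normal(0.2 * bx, 0.02)
    sy = rng.uniform(0.01, 0.05, n)
    return make_harmonised(bx, sx, by, sy, outcome_type=outcome_type)


class TestWaldRatio:
    def test_arithmetic(self):
        r = wald_ratio(0.5, 0.01, 0.1, 0.02)
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.04)

    def test_null_outcome(self):
        r = wald_ratio(0.5, 0.01, 0.0, 0.02)
        assert r.beta == 0.0 and r.pval == pytest.approx(1.0)

    def test_sign_symmetry(self):
        a = wald_ratio(0.5, 0.01, 0.1, 0.02)
        b = wald_ratio(-0.5, 0.01, 0.1, 0.02)
        assert b.beta == pytest.approx(-a.beta)
        assert b.se == pytest.approx(a.se)

    def test_degenerate_instrument(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIVW:
    def test_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(1)
        h = random_harmonised(rng, 3)
        bx, sy = h.aligned["beta_exp"], h.aligned["se_out"]
        ratios = h.aligned["beta_out"] / bx
        w = bx ** 2 / sy ** 2
        oracle = float(np.sum(w * ratios) / np.sum(w))
        assert ivw(h, "fixed").beta == pytest.approx(oracle, rel=1e-12)

    def test_duplicated_pair_equals_wald(self):
        h = make_harmonised([0.2, 0.2], [0.01, 0.01], [0.05, 0.05],
                            [0.02, 0.02])
        assert ivw(h, "fixed").beta == pytest.approx(0.05 / 0.2)

    def test_random_effects_floor(self):
        # exactly proportional effects: Q = 0, so RE se equals FE se
        h = make_harmonised([0.1, 0.2, 0.4], [0.01] * 3, [0.03, 0.06, 0.12],
                            [0.02] * 3)
        assert ivw(h, "random").se == pytest.approx(ivw(h, "fixed").se)

    def test_heterogeneity_inflates_re_se(self):
        h = make_harmonised([0.1, 0.2, 0.4], [0.01] * 3, [0.3, -0.2, 0.12],
                            [0.02] * 3)
        assert ivw(h, "random").se > ivw(h, "fixed").se

    def test_single_instrument_routed_away(self):
        h = make_harmonised([0.2], [0.01], [0.05], [0.02])
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(h)


class TestEgger:
    def test_exact_linear_recovery(self):
        bx = np.array([0.1, 0.15, 0.22, 0.3, 0.41])
        by = 0.05 + 0.3 * bx
        h = make_harmonised(bx, np.full(5, 0.01), by, np.full(5, 0.02))
        slope, intercept, se_int, p_int = egger(h)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept == pytest.approx(0.05, abs=1e-12)

    def test_balanced_pleiotropy_zero_intercept(self):
        bx = np.array([0.1, 0.1, 0.2, 0.2])
        by = 0.3 * bx + np.array([0.02, -0.02, 0.02, -0.02])
        h = make_harmonised(bx, np.full(4, 0.01), by, np.full(4, 0.02))
        _, intercept, _, _ = egger(h)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_orientation_invariance(self):
        bx = np.array([0.1, -0.15, 0.22, -0.3])
        by = 0.05 * np.sign(bx) * 0 + 0.3 * bx  # pure slope
        h = make_harmonised(bx, np.full(4, 0.01), by, np.full(4, 0.02))
        slope, intercept, *_ = egger(h)
        assert slope.beta == pytest.approx(0.3, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_needs_three(self):
        h = make_harmonised([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.02] * 2)
        with pytest.raises(ValueError):
            egger(h)

    def test_intercept_test_calibrated(self):
        """Under no pleiotropy the intercept test rejects at ~5%."""
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 500
        for _ in range(reps):
            bx_true = rng.uniform(0.05, 0.3, 12)
            bx = rng.normal(bx_true, 0.01)
            by = rng.normal(0.2 * bx_true, 0.02)
            h = make_harmonised(bx, np.full(12, 0.01), by, np.full(12, 0.02))
            *_, p_int = egger(h)
            rejections += p_int < 0.05
        assert 0.02 < rejections / reps < 0.09


class TestMedianMode:
    def test_equal_weights_weighted_equals_simple(self):
        h = make_harmonised([0.2] * 5, [1e-12] * 5,
                            [0.02, 0.04, 0.05, 0.07, 0.18], [0.02] * 5)
        s = median_estimator(h, "simple", n_boot=200, seed=3)
        w = median_estimator(h, "weighted", n_boot=200, seed=3)
        assert s.beta == pytest.approx(w.beta)

    def test_odd_count_median(self):
        h = make_harmonised([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.9],
                            [0.02] * 3)
        assert median_estimator(h, "simple", n_boot=200, seed=0).beta == \
            pytest.approx(0.2)

    def test_weighted_median_cumulative_oracle(self):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.1, 0.4, 5)
        by = rng.normal(0.25 * bx, 0.03)
        sx = np.full(5, 0.01)
        sy = rng.uniform(0.01, 0.04, 5)
        h = make_harmonised(bx, sx, by, sy)
        est = median_estimator(h, "weighted", n_boot=200, seed=5).beta
        # brute-force definition: order ratios, interpolate the weighted CDF
        ratios = by / bx
        w = 1.0 / (sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4)
        order = np.argsort(ratios)
        r_s, w_s = ratios[order], w[order] / w.sum()
        cum = np.cumsum(w_s) - w_s / 2
        k = np.searchsorted(cum, 0.5)
        expected = r_s[k - 1] + (0.5 - cum[k - 1]) * \
            (r_s[k] - r_s[k - 1]) / (cum[k] - cum[k - 1])
        assert est == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_determinism(self):
        h = make_harmonised([0.2, 0.3, 0.15, 0.22], [0.01] * 4,
                            [0.05, 0.06, 0.03, 0.05], [0.02] * 4)
        a = median_estimator(h, "weighted", n_boot=300, seed=9)
        b = median_estimator(h, "weighted", n_boot=300, seed=9)
        assert a.se == b.se
        c = mode_estimator(h, "weighted", n_boot=300, seed=9)
        d = mode_estimator(h, "weighted", n_boot=300, seed=9)
        assert c.se == d.se

    def test_low_boot_warns(self):
        h = make_harmonised([0.2, 0.3, 0.15], [0.01] * 3,
                            [0.05, 0.06, 0.03], [0.02] * 3)
        with pytest.warns(UserWarning):
            median_estimator(h, "simple", n_boot=50, seed=0)

    def test_mode_identical_ratios(self):
        h = make_harmonised([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.1, 0.2],
                            [0.02] * 3)
        assert mode_estimator(h, "simple", n_boot=100, seed=0).beta == \
            pytest.approx(0.5)

    def test_mode_robust_to_outlier(self):
        h = make_harmonised([1.0] * 4, [0.01] * 4, [0.2, 0.2, 0.2, 5.0],
                            [0.02] * 4)
        est = mode_estimator(h, "simple", n_boot=100, seed=0).beta
        assert abs(est - 0.2) < 0.05

    def test_zero_bandwidth_rejected(self):
        h = make_harmonised([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.2],
                            [0.02] * 3)
        with pytest.raises(ValueError):
            mode_estimator(h, bandwidth_factor=0.0)


class TestMaxLikelihood:
    def test_limiting_case_equals_ivw_fixed(self):
        rng = np.random.default_rng(7)
        h = random_harmonised(rng, 8)
        h.aligned["se_exp"] = 1e-8
        ml = max_likelihood(h)
        assert ml.beta == pytest.approx(ivw(h, "fixed").beta, abs=1e-6)
        assert ml.converged

    def test_exact_slope_recovered(self):
        bx = np.array([0.1, 0.2, 0.35])
        h = make_harmonised(bx, [0.01] * 3, 0.4 * bx, [0.02] * 3)
        assert max_likelihood(h).beta == pytest.approx(0.4, abs=1e-8)

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(200):
            bx_true = rng.uniform(0.1, 0.3, 10)
            bx = rng.normal(bx_true, 0.01)
            by = rng.normal(0.0, 0.02, 10)
            h = make_harmonised(bx, np.full(10, 0.01), by, np.full(10, 0.02))
            r = max_likelihood(h)
            hits += abs(r.beta) <= 2 * r.se
        assert hits / 200 >= 0.93


class TestCochranQ:
    def test_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonised(bx, [0.01] * 3, 0.3 * bx, [0.02] * 3)
        q, p = cochran_q(h, 0.3)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_hand_computed(self):
        h = make_harmonised([0.2, 0.4], [0.01] * 2, [0.06, 0.08], [0.02] * 2)
        # ratios 0.3, 0.2; weights (0.2/0.02)^2=100, (0.4/0.02)^2=400
        q, _ = cochran_q(h, 0.25)
        assert q == pytest.approx(100 * 0.05 ** 2 + 400 * 0.05 ** 2)

    def test_null_uniformity(self):
        from scipy import stats as st
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(400):
            bx = rng.normal(rng.uniform(0.1, 0.3, 10), 0.01)
            by = rng.normal(0.2 * bx, 0.02)
            h = make_harmonised(bx, np.full(10, 0.01), by, np.full(10, 0.02))
            pvals.append(cochran_q(h, ivw(h, "fixed").beta)[1])
        assert st.kstest(pvals, "uniform").pvalue > 0.01


class TestLeaveOneOutAndSuite:
    def test_cardinality(self):
        rng = np.random.default_rng(10)
        h = random_harmonised(rng, 5)
        results, loo, _ = leave_one_out(h)
        assert len(results) == 5 and len(loo) == 5

    def test_planted_driver_found(self):
        # one high-precision SNP carries essentially all the evidence:
        # dropping it lifts the p-value above 0.05
        bx = np.array([0.1, 0.1, 0.1, 0.1, 0.6])
        by = 0.3 * bx
        sy = np.array([0.05, 0.05, 0.05, 0.05, 0.01])
        h = make_harmonised(bx, np.full(5, 0.01), by, sy)
        _, _, driver = leave_one_out(h)
        assert driver == "rs4"

    def test_homogeneous_no_driver(self):
        bx = np.full(5, 0.3)
        h = make_harmonised(bx, np.full(5, 0.01), 0.4 * bx, np.full(5, 0.005))
        _, _, driver = leave_one_out(h)
        assert driver is None

    def test_bidirectional_flag(self):
        f = wald_ratio(0.3, 0.01, 0.12, 0.01)   # strongly significant
        weak = wald_ratio(0.3, 0.01, 0.001, 0.01)
        assert not bidirectional(f, weak, alpha=0.05)
        sig = wald_ratio(0.3, 0.01, 0.1, 0.012)
        assert bidirectional(f, sig, alpha=0.05)

    def test_boundary_is_strict(self):
        from scipy import stats as st
        f = wald_ratio(0.3, 0.01, 0.12, 0.01)
        border = wald_ratio(1.0, 0.0001, st.norm.isf(0.025), 1.0)
        assert border.pval == pytest.approx(0.05, rel=1e-10)
        assert not bidirectional(f, border, alpha=border.pval)

    def test_suite_routes_single_iv_to_wald(self):
        h = make_harmonised([0.2], [0.01], [0.06], [0.02],
                            outcome_type="binary")
        primary, sens, verdict = run_mr_suite(h, n_boot=100, seed=0)
        assert primary.method == "wald_ratio"
        assert primary.or_sd is not None
        assert primary.or_sd[0] == pytest.approx(np.exp(primary.beta))

    def test_suite_zero_instruments_not_testable(self):
        h = make_harmonised([], [], [], [])
        primary, _, verdict = run_mr_suite(h)
        assert primary is None and not verdict.testable

    def test_suite_clean_passes(self):
        rng = np.random.default_rng(11)
        bx_true = rng.uniform(0.1, 0.3, 10)
        bx = rng.normal(bx_true, 0.005)
        by = rng.normal(0.3 * bx_true, 0.01)
        h = make_harmonised(bx, np.full(10, 0.005), by, np.full(10, 0.01))
        primary, sens, verdict = run_mr_suite(h, n_boot=150, seed=1)
        assert verdict.passed, verdict.reasons
        assert sens.method_concordance

    @given(scale=st.floats(0.2, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_estimator_equivariance(self, scale):
        """Scaling all outcome effects by c scales every estimate by c."""
        rng = np.random.default_rng(12)
        h = random_harmonised(rng, 6)
        h2 = make_harmonised(h.aligned["beta_exp"], h.aligned["se_exp"],
                             scale * h.aligned["beta_out"],
                             scale * h.aligned["se_out"])
        for fn in (lambda g: ivw(g, "random"),
                   lambda g: median_estimator(g, "weighted", 150, 3),
                   lambda g: max_likelihood(g)):
            assert fn(h2).beta == pytest.approx(scale * fn(h).beta,
                                                rel=1e-6, abs=1e-9)
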