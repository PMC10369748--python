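"""Estimator suite: closed-form trivia, independent weighted-least-squares
oracles (statsmodels), reduction of multivariable to univariable estimators,
robust-estimator behaviour, and scale equivariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mviv.errors import CollinearityError, EmptyResultError
from mviv.estimators import (
    cochran_q, conditional_f, ivw, mr_egger, mv_egger, mv_ivw, mv_median,
    mv_mode, results_to_frame, wald_ratios, weighted_median, weighted_mode,
)

from conftest import make_harmonised


def _wls_oracle(X, y, w):
    """Independent WLS oracle via statsmodels."""
    import statsmodels.api as sm

    return sm.WLS(y, X, weights=w).fit()


class TestWaldRatios:
    def test_ratio_and_se(self):
        h = make_harmonised([0.1], [0.01], [0.2], [0.05])
        r, se, _ = wald_ratios(h)
        assert r[0] == pytest.approx(2.0)
        assert se[0] == pytest.approx(0.5)

    def test_negative_exposure_beta_sign_handling(self):
        h = make_harmonised([-0.1], [0.01], [0.2], [0.05])
        r, se, _ = wald_ratios(h)
        assert r[0] == pytest.approx(-2.0)
        assert se[0] == pytest.approx(0.5)  # SE positive regardless of sign

    def test_zero_exposure_beta_dropped(self):
        h = make_harmonised([0.1, 0.0, 0.2], [0.01] * 3,
                            [0.2, 0.5, 0.3], [0.05] * 3)
        r, se, keep = wald_ratios(h)
        assert len(r) == 2
        assert not keep[1]

    def test_three_variant_hand_computation(self):
        bx, by, sey = [0.1, 0.2, -0.05], [0.05, 0.02, 0.01], [0.01, 0.02, 0.03]
        h = make_harmonised(bx, [0.01] * 3, by, sey)
        r, se, _ = wald_ratios(h)
        np.testing.assert_allclose(r, [0.5, 0.1, -0.2])
        np.testing.assert_allclose(se, [0.1, 0.1, 0.6])


class TestIvw:
    def test_homogeneous_ratios_recovered_with_zero_q(self):
        bx = np.array([0.1, 0.2, 0.15])
        h = make_harmonised(bx, [0.01] * 3, 0.5 * bx, [0.01] * 3)
        res = ivw(h)
        assert res.estimate == pytest.approx(0.5, abs=1e-12)
        assert res.q_statistic == pytest.approx(0.0, abs=1e-18)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_matches_wls_oracle(self):
        bx = np.array([0.1, 0.2, 0.15])
        by = np.array([0.11, 0.19, 0.16])
        sey = np.array([0.01, 0.01, 0.01])
        res = ivw(make_harmonised(bx, [0.01] * 3, by, sey))
        fit = _wls_oracle(bx[:, None], by, 1.0 / sey**2)
        assert res.estimate == pytest.approx(fit.params[0], abs=1e-10)

    def test_equals_wald_ratio_meta_analysis(self, toy_harmonised):
        res = ivw(toy_harmonised)
        r, se, _ = wald_ratios(toy_harmonised)
        w = 1.0 / se**2
        assert res.estimate == pytest.approx(np.sum(w * r) / np.sum(w), rel=1e-12)

    def test_overdispersion_floor(self, toy_harmonised):
        res = ivw(toy_harmonised)
        bx = toy_harmonised.exposure_beta
        w = 1.0 / toy_harmonised.outcome_se**2
        se_fixed = np.sqrt(1.0 / np.sum(w * bx**2))
        assert res.se >= se_fixed - 1e-15

    def test_empty_set_rejected(self):
        with pytest.raises((EmptyResultError, ValueError)):
            make_harmonised([], [], [], [])


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.linspace(0.05, 0.3, 8)
        by = 0.01 + 0.3 * bx
        res = mr_egger(make_harmonised(bx, [0.01] * 8, by, [0.02] * 8))
        assert res.estimate == pytest.approx(0.3, abs=1e-8)
        assert res.egger_intercept == pytest.approx(0.01, abs=1e-8)

    def test_orientation_invariance(self, toy_harmonised):
        res = mr_egger(toy_harmonised)
        h2 = make_harmonised(
            toy_harmonised.exposure_beta * np.array([-1, 1, -1, 1, 1]),
            toy_harmonised.exposure_se,
            toy_harmonised.outcome_beta * np.array([-1, 1, -1, 1, 1]),
            toy_harmonised.outcome_se,
        )
        assert mr_egger(h2).estimate == pytest.approx(res.estimate, rel=1e-12)
        assert mr_egger(h2).egger_intercept == pytest.approx(
            res.egger_intercept, rel=1e-12)

    def test_matches_wls_oracle_after_orientation(self, rng):
        bx = rng.uniform(0.05, 0.3, 10)
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.01, 10)
        sey = rng.uniform(0.01, 0.03, 10)
        res = mr_egger(make_harmonised(bx, [0.01] * 10, by, sey))
        X = np.column_stack([np.ones(10), bx])
        fit = _wls_oracle(X, by, 1.0 / sey**2)
        assert res.estimate == pytest.approx(fit.params[1], abs=1e-10)
        assert res.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)

    def test_too_few_variants(self):
        with pytest.raises(EmptyResultError):
            mr_egger(make_harmonised([0.1, 0.2], [0.01] * 2,
                                     [0.1, 0.2], [0.01] * 2))


class TestWeightedMedian:
    def test_equal_weights_odd_ratios(self):
        bx = np.ones(3) * 0.1
        by = 0.1 * np.array([1.0, 2.0, 9.0])
        h = make_harmonised(bx, [0.01] * 3, by, [0.01] * 3)
        res = weighted_median(h, n_boot=50, seed=1)
        assert res.estimate == pytest.approx(2.0, abs=1e-9)

    def test_dominant_weight_pulls_estimate(self):
        # weights ~ (0.98, 0.01, 0.01) on ratios (5, 1, 2)
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.5, 0.1, 0.2])
        sey = 0.1 * np.array([np.sqrt(1 / 0.98), np.sqrt(1 / 0.01), np.sqrt(1 / 0.01)])
        h = make_harmonised(bx, [0.001] * 3, by, sey)
        res = weighted_median(h, n_boot=50, seed=1)
        # independent evaluation of the interpolation formula
        r = np.array([1.0, 2.0, 5.0])
        w = np.array([0.01, 0.01, 0.98])
        cum = np.cumsum(w) - 0.5 * w
        expected = np.interp(0.5, cum, r)
        assert res.estimate == pytest.approx(expected, rel=1e-9)
        assert res.estimate > 4.5

    def test_breakdown_under_directional_pleiotropy(self, rng):
        """With 40% invalid instruments, the weighted median stays near the
        true ratio while IVW is dragged away."""
        m, theta = 30, 0.5
        bx = rng.uniform(0.1, 0.3, m)
        pleio = np.where(np.arange(m) < 12, 0.08, 0.0)  # directional offsets
        by = theta * bx + pleio + rng.normal(0, 0.002, m)
        h = make_harmonised(bx, [0.005] * m, by, [0.005] * m)
        med = weighted_median(h, n_boot=50, seed=2).estimate
        naive = ivw(h).estimate
        assert abs(med - theta) < abs(naive - theta) / 2


class TestWeightedMode:
    def test_majority_cluster(self):
        bx = np.full(4, 0.1)
        by = 0.1 * np.array([2.0, 2.01, 1.99, 7.0])
        h = make_harmonised(bx, [0.01] * 4, by, [0.01] * 4)
        res = weighted_mode(h, n_boot=30, seed=3)
        assert res.estimate == pytest.approx(2.0, abs=0.1)

    def test_cluster_with_outlier(self):
        bx = np.full(6, 0.1)
        by = 0.1 * np.array([1.0, 1.02, 0.98, 1.01, 0.99, 8.0])
        res = weighted_mode(make_harmonised(bx, [0.01] * 6, by, [0.01] * 6),
                            n_boot=30, seed=3)
        assert res.estimate == pytest.approx(1.0, abs=0.1)

    def test_large_bandwidth_limit_is_weighted_mean(self):
        bx = np.full(5, 0.1)
        by = 0.1 * np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        sey = np.array([0.01, 0.02, 0.01, 0.03, 0.01])
        h = make_harmonised(bx, [0.001] * 5, by, sey)
        r, se_r, _ = wald_ratios(h)
        w = 1.0 / se_r**2
        wmean = np.sum(w * r) / np.sum(w)
        res = weighted_mode(h, bandwidth_factor=2000.0, n_boot=10, seed=1,
                            grid_size=200_001)
        assert res.estimate == pytest.approx(wmean, abs=0.05)

    def test_degenerate_identical_ratios(self):
        bx = np.full(3, 0.1)
        h = make_harmonised(bx, [0.01] * 3, 0.5 * bx, [0.01] * 3)
        assert weighted_mode(h, n_boot=10, seed=0).estimate == pytest.approx(0.5)


class TestCochranQ:
    def test_zero_when_ratios_equal_theta(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonised(bx, [0.01] * 3, 0.7 * bx, [0.01] * 3)
        q, df, p = cochran_q(h, 0.7)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic_two_ratios(self):
        # ratios (0, 2) with unit ratio-SEs, theta = 1 -> Q = 1 + 1 = 2
        h = make_harmonised([1.0, 1.0], [0.01] * 2, [0.0, 2.0], [1.0, 1.0])
        q, df, p = cochran_q(h, 1.0)
        assert q == pytest.approx(2.0, rel=1e-12)
        assert df == 1

    def test_chi2_distribution_under_homogeneity(self, rng):
        """Homogeneous simulated ratios: Q ~ chi2(n-1), so the mean over
        replicates is close to n-1."""
        m, reps = 10, 400
        qs = []
        for _ in range(reps):
            bx = rng.uniform(0.2, 0.5, m)
            sey = np.full(m, 0.01)
            by = 0.3 * bx + rng.normal(0, 1, m) * sey
            h = make_harmonised(bx, [1e-6] * m, by, sey)
            est = ivw(h).estimate
            qs.append(cochran_q(h, est)[0])
        # fitting theta absorbs one df
        assert np.mean(qs) == pytest.approx(m - 1, rel=0.1)


class TestMultivariable:
    def test_zero_covariate_column_reduces_to_ivw(self, toy_harmonised):
        h = make_harmonised(
            toy_harmonised.exposure_beta, toy_harmonised.exposure_se,
            toy_harmonised.outcome_beta, toy_harmonised.outcome_se,
            bp=np.zeros(5), sep=np.full(5, 0.01),
        )
        uv = ivw(toy_harmonised)
        mv = mv_ivw(h)
        assert mv[0].estimate == pytest.approx(uv.estimate, abs=1e-14)
        assert mv[1].estimate == 0.0

    def test_zero_covariate_column_reduces_other_estimators(self, toy_harmonised):
        h = make_harmonised(
            toy_harmonised.exposure_beta, toy_harmonised.exposure_se,
            toy_harmonised.outcome_beta, toy_harmonised.outcome_se,
            bp=np.zeros(5), sep=np.full(5, 0.01),
        )
        assert mv_egger(h)[0].estimate == pytest.approx(
            mr_egger(toy_harmonised).estimate, abs=1e-12)
        assert mv_median(h, n_boot=40, seed=9)[0].estimate == pytest.approx(
            weighted_median(toy_harmonised, n_boot=40, seed=9).estimate, abs=1e-12)
        assert mv_mode(h, n_boot=20, seed=9)[0].estimate == pytest.approx(
            weighted_mode(toy_harmonised, n_boot=20, seed=9).estimate, abs=1e-12)

    def test_four_variant_wls_oracle(self):
        bx = np.array([0.10, 0.20, 0.15, 0.05])
        bp = np.array([0.02, -0.01, 0.03, 0.08])
        by = np.array([0.12, 0.18, 0.17, 0.09])
        sey = np.array([0.01, 0.02, 0.01, 0.015])
        h = make_harmonised(bx, [0.01] * 4, by, sey, bp=bp, sep=[0.01] * 4)
        res = mv_ivw(h)
        fit = _wls_oracle(np.column_stack([bx, bp]), by, 1.0 / sey**2)
        assert res[0].estimate == pytest.approx(fit.params[0], abs=1e-10)
        assert res[1].estimate == pytest.approx(fit.params[1], abs=1e-10)

    def test_noiseless_two_exposure_recovery(self):
        rng = np.random.default_rng(4)
        m = 20
        bx = rng.uniform(0.05, 0.3, m)
        bp = rng.uniform(-0.2, 0.2, m)
        by = 0.7 * bx - 0.4 * bp
        h = make_harmonised(bx, [0.01] * m, by, [0.01] * m,
                            bp=bp, sep=[0.01] * m)
        for res in (mv_ivw(h), mv_egger(h), mv_median(h, n_boot=20, seed=0)):
            assert res[0].estimate == pytest.approx(0.7, abs=1e-6)
            assert res[1].estimate == pytest.approx(-0.4, abs=1e-6)
        modes = mv_mode(h, n_boot=10, seed=0)
        assert modes[0].estimate == pytest.approx(0.7, abs=5e-3)
        assert modes[1].estimate == pytest.approx(-0.4, abs=5e-3)

    def test_collinear_design_raises_with_condition_number(self):
        bx = np.array([0.1, 0.2, 0.15, 0.05])
        h = make_harmonised(bx, [0.01] * 4, 0.5 * bx, [0.01] * 4,
                            bp=2 * bx, sep=[0.01] * 4)
        with pytest.raises(CollinearityError):
            mv_ivw(h)

    def test_mv_robust_estimators_resist_invalid_minority(self, rng):
        """A pleiotropic minority biases MV-IVW; the conditional-ratio median
        stays closer to the truth."""
        m = 30
        bx = rng.uniform(0.1, 0.3, m)
        bp = rng.uniform(-0.1, 0.1, m)
        direct = np.where(np.arange(m) < 9, 0.12, 0.0)
        by = 0.5 * bx + 0.3 * bp + direct + rng.normal(0, 0.002, m)
        h = make_harmonised(bx, [0.005] * m, by, [0.005] * m,
                            bp=bp, sep=[0.005] * m)
        est_ivw = mv_ivw(h)[0].estimate
        est_med = mv_median(h, n_boot=30, seed=5)[0].estimate
        assert abs(est_med - 0.5) < abs(est_ivw - 0.5)


class TestConditionalF:
    def test_single_exposure_degenerate_convention(self, toy_harmonised):
        f = conditional_f(toy_harmonised, 0)
        z2 = (toy_harmonised.exposure_beta / toy_harmonised.exposure_se) ** 2
        assert f == pytest.approx(z2.mean(), rel=1e-12)

    def test_orthogonal_strong_instruments(self, rng):
        m = 50
        bx = rng.normal(0.15, 0.05, m)
        bp = rng.normal(0.0, 0.05, m)  # uncorrelated with bx
        h = make_harmonised(bx, [0.01] * m, 0.5 * bx, [0.01] * m,
                            bp=bp, sep=[0.01] * m)
        f_cond = conditional_f(h, 0)
        f_uncond = np.mean((bx / 0.01) ** 2)
        assert f_cond == pytest.approx(f_uncond, rel=0.25)
        assert f_cond > 100

    def test_collinear_exposures_have_no_conditional_strength(self):
        bx = np.array([0.1, 0.2, 0.15, 0.05])
        h = make_harmonised(bx, [0.01] * 4, 0.5 * bx, [0.01] * 4,
                            bp=3 * bx, sep=[0.01] * 4)
        assert conditional_f(h, 0) == pytest.approx(0.0, abs=1e-12)


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [2.0, 0.25])
    def test_outcome_rescaling_rescales_estimates(self, toy_harmonised, c):
        h = toy_harmonised
        hc = make_harmonised(h.exposure_beta, h.exposure_se,
                             c * h.outcome_beta, c * h.outcome_se)
        assert ivw(hc).estimate == pytest.approx(c * ivw(h).estimate, rel=1e-10)
        assert ivw(hc).se == pytest.approx(c * ivw(h).se, rel=1e-10)
        assert mr_egger(hc).estimate == pytest.approx(
            c * mr_egger(h).estimate, rel=1e-10)
        med_c = weighted_median(hc, n_boot=60, seed=11)
        med = weighted_median(h, n_boot=60, seed=11)
        assert med_c.estimate == pytest.approx(c * med.estimate, rel=1e-10)
        assert med_c.se == pytest.approx(c * med.se, rel=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_weighted_regressions_match_normal_equations_oracle(seed):
    """Property: on random small instances every weighted-regression
    estimator agrees with an independently coded brute-force normal-equations
    solve to 1e-8."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(4, 12))
    bx = rng.normal(0.1, 0.08, m)
    bp = rng.normal(0.05, 0.08, m)
    by = rng.normal(0.0, 0.1, m)
    sey = rng.uniform(0.01, 0.1, m)
    h_uv = make_harmonised(bx, np.full(m, 0.01), by, sey)
    h_mv = make_harmonised(bx, np.full(m, 0.01), by, sey,
                           bp=bp, sep=np.full(m, 0.01))
    w = 1.0 / sey**2

    def solve(X):
        # brute-force normal equations with explicit weight matrix
        W = np.diag(w)
        return np.linalg.solve(X.T @ W @ X, X.T @ W @ by)

    assert ivw(h_uv).estimate == pytest.approx(solve(bx[:, None])[0], abs=1e-8)
    ones = np.ones(m)
    s = np.where(bx < 0, -1.0, 1.0)
    egger_coef = np.linalg.solve(
        np.column_stack([ones, s * bx]).T @ np.diag(w) @ np.column_stack([ones, s * bx]),
        np.column_stack([ones, s * bx]).T @ np.diag(w) @ (s * by),
    )
    assert mr_egger(h_uv).estimate == pytest.approx(egger_coef[1], abs=1e-8)
    mv_coef = solve(np.column_stack([bx, bp]))
    res = mv_ivw(h_mv)
    assert res[0].estimate == pytest.approx(mv_coef[0], abs=1e-8)
    assert res[1].estimate == pytest.approx(mv_coef[1], abs=1e-8)


def test_results_frame_layout(toy_harmonised):
    frame = results_to_frame([ivw(toy_harmonised), mr_egger(toy_harmonised)])
    assert list(frame["method"]) == ["IVW", "MR-Egger"]
    for col in ("estimate", "se", "ci_low", "ci_high", "pvalue", "n_snps"):
        assert col in frame.columns
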