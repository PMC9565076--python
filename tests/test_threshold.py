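"""Two-regime threshold estimator: grid, SSR, LR, CI, bootstrap, prediction."""

import math

import numpy as np
import pytest

from cdwheat import (
    ConfigurationError,
    DegenerateThresholdError,
    DegenerateVarianceError,
    ThresholdFit,
    ThresholdSpec,
    bootstrap_test,
    build_grid,
    fit_all,
    fit_linear_baseline,
    fit_threshold,
    gamma_ci,
    lr_critical_value,
    lr_sequence,
    predict,
    ssr_at,
)
from cdwheat.threshold import models_frame

from conftest import make_frame

SPEC = ThresholdSpec(response="y", predictor="x", threshold_var="q")


def _simple_ols_ssr(x, y):
    """Closed-form simple-regression SSR, the hand oracle for ssr_at."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    return syy - sxy ** 2 / sxx


class TestBuildGrid:
    def test_trimming_keeps_interior_positions(self):
        q = np.arange(1.0, 21.0)  # 1..20
        spec = ThresholdSpec("y", "x", "q", trim_fraction=0.15,
                             min_regime_size=3)
        grid = build_grid(q, spec)
        # ceil(0.15*20)=3 observations per side -> candidates at sorted
        # positions 3..17 (values 3..17)
        np.testing.assert_array_equal(grid, np.arange(3.0, 18.0))

    def test_constant_threshold_variable_is_degenerate(self):
        with pytest.raises(DegenerateThresholdError):
            build_grid(np.ones(10), SPEC)

    def test_study_scale_trimming(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=22)
        grid = build_grid(q, SPEC)
        n_min = math.ceil(0.15 * 22)  # = 4
        assert n_min == 4
        for g in (grid[0], grid[-1]):
            assert (q <= g).sum() >= n_min and (q > g).sum() >= n_min

    def test_ties_assigned_to_lower_regime(self):
        q = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0,
                      4.0, 4.0])
        spec = ThresholdSpec("y", "x", "q", trim_fraction=0.2,
                             min_regime_size=3)
        grid = build_grid(q, spec)
        for g in grid:
            assert (q <= g).sum() >= 3 and (q > g).sum() >= 3


class TestSsrAt:
    def test_identical_noiseless_regimes_have_zero_ssr(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        q = rng.normal(size=30)
        y = 2.0 + 3.0 * x
        frame = make_frame(y, x, q)
        grid = build_grid(q, SPEC)
        out = ssr_at(frame, SPEC, grid[len(grid) // 2])
        assert out["ssr"] == pytest.approx(0.0, abs=1e-18)
        assert out["beta_low"] == pytest.approx(out["beta_high"], abs=1e-9)

    def test_matches_two_hand_computed_regressions(self):
        # 8-point frame, split at q <= 4
        x = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        q = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([1.1, 2.3, 2.8, 4.2, 9.5, 7.1, 5.2, 2.9])
        spec = ThresholdSpec("y", "x", "q", trim_fraction=0.4,
                             min_regime_size=3)
        out = ssr_at(make_frame(y, x, q), spec, 4.0)
        expected = _simple_ols_ssr(x[:4], y[:4]) + _simple_ols_ssr(x[4:], y[4:])
        assert out["ssr"] == pytest.approx(expected, rel=1e-12)
        assert (out["n_low"], out["n_high"]) == (4, 4)

    def test_regime_fits_match_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 30
        q = rng.uniform(size=n)
        x = rng.normal(size=n)
        y = np.where(q <= 0.5, 1 + x, 2 - x) + rng.normal(0, 0.4, n)
        frame = make_frame(y, x, q)
        grid = build_grid(q, SPEC)
        g = grid[len(grid) // 2]
        out = ssr_at(frame, SPEC, g)
        low = q <= g
        ref_low = sm.OLS(y[low], sm.add_constant(x[low])).fit()
        ref_high = sm.OLS(y[~low], sm.add_constant(x[~low])).fit()
        assert out["beta_low"] == pytest.approx(tuple(ref_low.params), rel=1e-9)
        assert out["beta_high"] == pytest.approx(tuple(ref_high.params), rel=1e-9)
        assert out["ssr"] == pytest.approx(ref_low.ssr + ref_high.ssr, rel=1e-9)

    def test_inadmissible_gamma_is_rejected(self):
        rng = np.random.default_rng(2)
        frame = make_frame(rng.normal(size=20), rng.normal(size=20),
                           np.arange(20.0))
        with pytest.raises(ValueError, match="admissible"):
            ssr_at(frame, SPEC, -10.0)


class TestFitThreshold:
    def test_recovers_planted_threshold_and_slopes(self):
        rng = np.random.default_rng(11)
        n = 200
        q = rng.uniform(0, 10, n)
        x = q
        y = np.where(q <= 5.0, -x, x) + rng.normal(0, 0.1, n)
        fit = fit_threshold(make_frame(y, x, q), SPEC)
        qs = np.sort(q)
        below = qs[qs <= 5.0][-1]
        assert fit.gamma_hat == pytest.approx(below)
        assert fit.beta_low[1] < 0 < fit.beta_high[1]
        assert fit.n_low + fit.n_high == n

    def test_noiseless_fit_recovers_coefficients_exactly(self):
        rng = np.random.default_rng(12)
        n = 60
        q = rng.uniform(0, 10, n)
        x = rng.normal(size=n)
        y = np.where(q <= 4.0, 1.5 + 2.0 * x, -0.5 - 1.0 * x)
        fit = fit_threshold(make_frame(y, x, q), SPEC)
        assert fit.beta_low == pytest.approx((1.5, 2.0), rel=1e-10)
        assert fit.beta_high == pytest.approx((-0.5, -1.0), rel=1e-10)
        qs = np.sort(q)
        assert fit.gamma_hat == pytest.approx(qs[qs <= 4.0][-1])
        assert fit.degenerate_variance  # perfect fit: no LR machinery

    def test_ssr_never_beats_null_and_argmin_is_global(self):
        rng = np.random.default_rng(13)
        for rep in range(5):
            n = 40
            q = rng.normal(size=n)
            x = rng.normal(size=n)
            y = np.where(q <= 0, 1 + x, 2 - x) + rng.normal(0, 0.5, n)
            frame = make_frame(y, x, q)
            fit = fit_threshold(frame, SPEC)
            base = fit_linear_baseline(frame, SPEC)
            assert np.all(fit.ssr_grid >= fit.ssr - 1e-9)
            assert np.all(base.ssr_null >= fit.ssr_grid - 1e-9)
            assert fit.ssr == pytest.approx(np.min(fit.ssr_grid), rel=1e-12)

    def test_per_regime_r2_matches_subset_ols(self):
        rng = np.random.default_rng(14)
        n = 80
        q = rng.uniform(size=n)
        x = rng.normal(size=n)
        y = np.where(q <= 0.5, x, 2 * x) + rng.normal(0, 0.3, n)
        fit = fit_threshold(make_frame(y, x, q), SPEC)
        low = q <= fit.gamma_hat
        ssr_low = _simple_ols_ssr(x[low], y[low])
        tss_low = ((y[low] - y[low].mean()) ** 2).sum()
        assert fit.r2_low == pytest.approx(1 - ssr_low / tss_low, rel=1e-9)


class TestLrSequence:
    def test_zero_at_the_estimate_and_nonnegative(self):
        rng = np.random.default_rng(20)
        n = 50
        q = rng.normal(size=n)
        x = rng.normal(size=n)
        y = np.where(q <= 0, x, -x) + rng.normal(0, 0.4, n)
        fit = fit_threshold(make_frame(y, x, q), SPEC)
        lr = np.array([v for _, v in fit.lr_sequence])
        k = int(np.argmin(np.abs(fit.grid - fit.gamma_hat)))
        assert lr[k] == 0.0
        assert np.all(lr >= 0)

    def test_formula_value(self):
        """LR = n (S - S_hat) / S_hat: direct evaluation on n=22, S=12,
        S_hat=10, checked against a fitted sequence at the same numbers."""
        assert 22 * (12 - 10) / 10 == pytest.approx(4.4)
        rng = np.random.default_rng(22)
        n = 50
        q = rng.normal(size=n)
        x = rng.normal(size=n)
        y = np.where(q <= 0, x, 1 - x) + rng.normal(0, 0.5, n)
        fit = fit_threshold(make_frame(y, x, q), SPEC)
        lr = np.array([v for _, v in fit.lr_sequence])
        np.testing.assert_allclose(
            lr, n * (fit.ssr_grid - fit.ssr) / fit.ssr, rtol=1e-9, atol=1e-9)

    def test_zero_noise_lr_is_degenerate(self):
        rng = np.random.default_rng(21)
        n = 40
        q = rng.normal(size=n)
        x = rng.normal(size=n)
        frame = make_frame(1 + 2 * x, x, q)
        fit = fit_threshold(frame, SPEC)
        with pytest.raises(DegenerateVarianceError):
            lr_sequence(fit)


class TestGammaCi:
    @pytest.mark.parametrize("alpha,expected", [
        (0.05, 7.3523), (0.10, 5.9394),
    ])
    def test_critical_values(self, alpha, expected):
        assert lr_critical_value(alpha) == pytest.approx(expected, abs=1e-4)

    def test_estimate_always_in_set(self):
        rng = np.random.default_rng(30)
        n = 60
        q = rng.uniform(size=n)
        x = rng.normal(size=n)
        y = np.where(q <= 0.5, x, 1 - x) + rng.normal(0, 0.5, n)
        fit = fit_threshold(make_frame(y, x, q), SPEC)
        ci = gamma_ci(fit, 0.05)
        assert ci["low"] <= fit.gamma_hat <= ci["high"]
        assert fit.gamma_hat in ci["members"]

    def test_flat_sequence_spans_grid(self):
        rng = np.random.default_rng(31)
        n = 60
        q = rng.uniform(size=n)
        x = rng.normal(size=n)
        y = 1 + 2 * x + rng.normal(0, 0.5, n)  # no threshold
        fit = fit_threshold(make_frame(y, x, q), SPEC)
        ci = gamma_ci(fit, 0.05)
        # under the null the LR sequence is shallow: the set is wide
        assert len(ci["members"]) > len(fit.grid) // 2


class TestBootstrap:
    def test_strong_threshold_is_detected(self):
        rng = np.random.default_rng(40)
        n = 200
        q = rng.uniform(0, 10, n)
        x = q
        y = np.where(q <= 5, x, -x) + rng.normal(0, 0.2, n)
        out = bootstrap_test(make_frame(y, x, q), SPEC, n_boot=199, seed=5)
        assert out["boot_p"] <= 0.01
        assert out["sup_stat"] > 0

    def test_determinism_under_fixed_seed(self, null_data):
        spec = ThresholdSpec("log_bcf", "ph", "ph")
        a = bootstrap_test(null_data, spec, n_boot=99, seed=9)
        b = bootstrap_test(null_data, spec, n_boot=99, seed=9)
        assert a == b

    def test_too_few_replicates_is_a_configuration_error(self, null_data):
        with pytest.raises(ConfigurationError):
            bootstrap_test(null_data, ThresholdSpec("log_bcf", "ph", "ph"),
                           n_boot=50)

    def test_p_value_never_zero(self):
        rng = np.random.default_rng(41)
        n = 100
        q = rng.uniform(0, 10, n)
        y = np.where(q <= 5, q, -q) + rng.normal(0, 0.1, n)
        out = bootstrap_test(make_frame(y, q, q), SPEC, n_boot=99, seed=1)
        assert out["boot_p"] >= 1 / 100


class TestPredict:
    # published regime equations for log[BCF] on pH with gamma = 7.98
    MODEL1 = ThresholdFit.from_coefficients(
        ThresholdSpec("log_bcf", "ph", "ph"), 7.98,
        beta_low=(-3.337, 0.292), beta_high=(4.186, -0.615))

    @pytest.mark.parametrize("ph,expected", [
        (7.5, -3.337 + 0.292 * 7.5),   # regime 1: -1.147
        (8.5, 4.186 - 0.615 * 8.5),    # regime 2: -1.0415
        (7.98, -3.337 + 0.292 * 7.98),  # boundary belongs to regime 1
    ])
    def test_published_regime_equations(self, ph, expected):
        assert predict(self.MODEL1, ph, ph) == pytest.approx(expected, abs=1e-12)

    def test_identity_model(self):
        fit = ThresholdFit.from_coefficients(SPEC, 0.0, (0.0, 1.0), (0.0, 1.0))
        x = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(predict(fit, x, x), x)

    def test_piecewise_consistency_with_regime_ols(self):
        rng = np.random.default_rng(50)
        n = 80
        q = rng.uniform(size=n)
        x = rng.normal(size=n)
        y = np.where(q <= 0.5, 1 + x, -1 + 2 * x) + rng.normal(0, 0.3, n)
        fit = fit_threshold(make_frame(y, x, q), SPEC)
        low = q <= fit.gamma_hat
        pred = predict(fit, x, q)
        a, b = fit.beta_low
        np.testing.assert_allclose(pred[low], a + b * x[low], rtol=1e-12)
        a, b = fit.beta_high
        np.testing.assert_allclose(pred[~low], a + b * x[~low], rtol=1e-12)


class TestFitAll:
    def test_generator_round_trip_recovers_ph_threshold(self):
        from cdwheat import SyntheticConfig, generate

        data = generate(SyntheticConfig(n=200, seed=5, noise_sd=0.1))
        spec = ThresholdSpec("log_bcf", "ph", "ph")
        fit = fit_threshold(data, spec)
        assert abs(fit.gamma_hat - 7.98) < 0.1
        assert fit.beta_low[1] > 0 > fit.beta_high[1]

    def test_empty_predictor_list_gives_empty_table(self, study_data):
        assert fit_all(study_data, [], ["ph"]) == []

    def test_cross_has_one_row_per_combination(self, study_data):
        results = fit_all(study_data, ["ph"], ["ph", "soil_cd"],
                          n_boot=99, seed=2)
        assert len(results) == 2
        frame = models_frame(results)
        assert set(frame["threshold_var"]) == {"ph", "soil_cd"}
        sig = frame[frame["significant"].fillna(False)]
        assert (sig["boot_p"] <= 0.05).all()

    def test_failing_combination_is_recorded_not_raised(self, study_data):
        frame = study_data.frame.copy()
        frame["const"] = 1.0
        from cdwheat import Dataset

        data = Dataset(frame=frame)
        results = fit_all(data, ["ph"], ["const"], n_boot=99)
        assert results[0]["fit"] is None
        assert "Degenerate" in results[0]["error"]
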