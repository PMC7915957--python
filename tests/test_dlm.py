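"""Lagged design construction, OLS fitting, multi-step simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biogasdlm import (
    BoundsError,
    FittedDLM,
    ModelConfig,
    SchemaError,
    SingularDesignError,
    build_design,
    fit_ols,
    simulate,
)

from conftest import make_series


def normal_equations(X, y):
    """Brute-force OLS oracle: (XᵀX)⁻¹Xᵀy."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def random_design_series(seed, n=600):
    rng = np.random.default_rng(seed)
    solid = np.where(rng.random(n) < 0.2, rng.uniform(200, 2500, n), 0.0)
    biogas = rng.uniform(30, 90, n)
    return make_series(solid, biogas)


class TestModelConfig:
    def test_grid_candidate_settings_accepted(self):
        cfg = ModelConfig(lag_order=96, training_length=800, horizon=144)
        assert cfg.n_params == 98

    def test_training_length_must_exceed_parameter_count(self):
        with pytest.raises(BoundsError):
            ModelConfig(lag_order=48, training_length=50)

    def test_zero_lag_is_plain_linear_regression(self):
        assert ModelConfig(lag_order=0, training_length=3).n_params == 2


class TestBuildDesign:
    def test_single_regressor_shape_500_by_50(self):
        series = random_design_series(0, n=600)
        d = build_design(series, ModelConfig(), train_end=599)
        assert d.matrix.shape == (500, 50)
        assert d.columns[:2] == ("intercept", "solid_feed_lag0")

    def test_two_regressor_shape_200_by_99(self):
        series = make_series(
            np.random.default_rng(1).uniform(0, 100, 300),
            np.random.default_rng(2).uniform(0, 100, 300),
            liquid=np.random.default_rng(3).uniform(0, 100, 300),
        )
        cfg = ModelConfig(
            training_length=200, regressors=("solid_feed", "liquid_feed")
        )
        d = build_design(series, cfg, train_end=299)
        assert d.matrix.shape == (200, 1 + 2 * 49)

    def test_zero_lag_design_is_intercept_and_current_feed(self):
        series = make_series([1.0, 2, 3, 4, 5], [10.0, 11, 12, 13, 14])
        d = build_design(
            series, ModelConfig(lag_order=0, training_length=3), train_end=4
        )
        np.testing.assert_array_equal(d.matrix[:, 0], 1.0)
        np.testing.assert_array_equal(d.matrix[:, 1], [3, 4, 5])
        np.testing.assert_array_equal(d.response, [12, 13, 14])

    def test_lagged_columns_align_with_history(self):
        series = make_series(np.arange(10.0), np.zeros(10) + 1)
        d = build_design(
            series, ModelConfig(lag_order=2, training_length=5), train_end=9
        )
        # row for hour t carries X(t), X(t-1), X(t-2)
        np.testing.assert_array_equal(d.matrix[:, 1], [5, 6, 7, 8, 9])
        np.testing.assert_array_equal(d.matrix[:, 2], [4, 5, 6, 7, 8])
        np.testing.assert_array_equal(d.matrix[:, 3], [3, 4, 5, 6, 7])

    def test_insufficient_warmup_raises(self):
        series = random_design_series(4, n=540)  # 500 + 48 needed, 540 available
        with pytest.raises(BoundsError, match="warm-up"):
            build_design(series, ModelConfig(), train_end=539)

    def test_absent_regressor_is_schema_error(self):
        series = random_design_series(5)
        cfg = ModelConfig(regressors=("solid_feed", "liquid_feed"))
        with pytest.raises(SchemaError, match="liquid_feed"):
            build_design(series, cfg, train_end=599)


class TestFitOLS:
    def test_noiseless_line_recovered_exactly(self):
        x = np.array([0.0, 1, 2, 3, 4, 5])
        series = make_series(x, 2.0 + 0.5 * x)
        model = fit_ols(
            build_design(series, ModelConfig(lag_order=0, training_length=6), 5)
        )
        assert model.intercept == pytest.approx(2.0, abs=1e-10)
        assert model.betas["solid_feed"][0] == pytest.approx(0.5, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 200, 8
        series = make_series(rng.uniform(0, 100, n + k), rng.uniform(20, 80, n + k))
        d = build_design(
            series, ModelConfig(lag_order=k, training_length=n), n + k - 1
        )
        model = fit_ols(d)
        expected = normal_equations(d.matrix, d.response)
        got = np.concatenate([[model.intercept], model.betas["solid_feed"]])
        np.testing.assert_allclose(got, expected, rtol=1e-8)

    def test_matches_statsmodels_cross_check(self):
        import statsmodels.api as sm

        series = random_design_series(9)
        d = build_design(series, ModelConfig(training_length=200), 599)
        model = fit_ols(d)
        ref = sm.OLS(d.response, d.matrix).fit()
        got = np.concatenate([[model.intercept], model.betas["solid_feed"]])
        np.testing.assert_allclose(got, ref.params, rtol=1e-7, atol=1e-10)

    def test_residuals_mean_zero(self):
        series = random_design_series(10)
        model = fit_ols(build_design(series, ModelConfig(), 599))
        assert abs(model.residuals.mean()) < 1e-8

    def test_zero_feeding_window_is_singular_and_names_columns(self):
        series = make_series(np.zeros(300), np.full(300, 60.0))
        with pytest.raises(SingularDesignError) as exc:
            fit_ols(build_design(series, ModelConfig(training_length=200), 299))
        assert any("solid_feed_lag" in c for c in exc.value.columns)

    def test_noiseless_synthetic_recovers_generating_kernel(self, noiseless_short):
        series, truth = noiseless_short
        model = fit_ols(build_design(series, ModelConfig(), len(series) - 1))
        assert model.intercept == pytest.approx(truth.alpha_true, abs=1e-6)
        np.testing.assert_allclose(
            model.betas["solid_feed"], truth.kernel, atol=1e-6
        )


def toy_model(beta, alpha=0.0, clamp=False):
    beta = np.asarray(beta, dtype=float)
    cfg = ModelConfig(
        lag_order=len(beta) - 1,
        training_length=len(beta) + 2,
        clamp_nonnegative=clamp,
    )
    return FittedDLM(
        intercept=alpha,
        betas={"solid_feed": beta},
        residuals=np.zeros(1),
        config=cfg,
        train_end=None,
    )


class TestSimulate:
    def test_zero_feed_zero_history_gives_constant_alpha(self):
        m = toy_model([0.1, 0.05, 0.02], alpha=45.0)
        np.testing.assert_allclose(
            simulate(m, np.zeros(10), np.zeros(2)), np.full(10, 45.0)
        )

    def test_negative_alpha_clamped_to_zero(self):
        m = toy_model([0.1], alpha=-3.0, clamp=True)
        np.testing.assert_array_equal(simulate(m, np.zeros(5)), np.zeros(5))

    def test_impulse_response_equals_beta_vector(self):
        beta = np.array([0.05, 0.03, 0.01, 0.005])
        m = toy_model(beta)
        feed = np.zeros(8)
        feed[0] = 1.0  # 1 kg pulse at future hour 0
        yhat = simulate(m, feed, np.zeros(3), clamp=False)
        np.testing.assert_allclose(yhat[:4], beta, atol=1e-14)
        np.testing.assert_allclose(yhat[4:], 0.0, atol=1e-14)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
        seed=st.integers(0, 10_000),
    )
    def test_simulation_is_linear_without_intercept_or_clamp(self, a, b, seed):
        rng = np.random.default_rng(seed)
        beta = rng.uniform(0, 0.1, 6)
        m = toy_model(beta)
        hist = rng.uniform(0, 100, 5)
        f1, f2 = rng.uniform(0, 100, (2, 12))
        combo = simulate(m, a * f1 + b * f2, (a + b) * hist, clamp=False)
        parts = a * simulate(m, f1, hist, clamp=False) + b * simulate(
            m, f2, hist, clamp=False
        )
        np.testing.assert_allclose(combo, parts, atol=1e-8)

    def test_forecast_matches_noiseless_generator(self, noiseless_short):
        series, truth = noiseless_short
        cfg = ModelConfig()
        origin = 1000
        model = fit_ols(build_design(series, cfg, origin))
        planned = series.solid_feed[origin + 1 : origin + 49]
        history = series.solid_feed[origin + 1 - 48 : origin + 1]
        yhat = simulate(model, planned, history)
        np.testing.assert_allclose(
            yhat, series.biogas[origin + 1 : origin + 49], atol=1e-6
        )

    def test_short_history_raises(self):
        m = toy_model([0.1, 0.1, 0.1])
        with pytest.raises(BoundsError, match="recent_history"):
            simulate(m, np.ones(5), np.ones(1))

    def test_regressor_mismatch_is_schema_error(self):
        m = toy_model([0.1, 0.1])
        with pytest.raises(SchemaError):
            simulate(m, {"liquid_feed": np.ones(5)}, {"liquid_feed": np.ones(1)})
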