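"""Maximum-likelihood fitting and profile-likelihood intervals."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from allomfit.data import Dataset
from allomfit.fitting import (
    AllometricRegression,
    _profile_loglik,
    fit,
    fit_pool,
    profile_ci,
)
from allomfit.models import back_transform_loglinear, evaluate_mean
from allomfit.synthdata import SimConfig, crab_like, generate


def _loglog_ols(x, y):
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    return intercept, slope


class TestZeroNoiseRecovery:
    @pytest.mark.parametrize("error", ["lognormal", "normal"])
    def test_line_exact(self, error):
        x = np.linspace(1.0, 10.0, 40)
        y = 1.0 + 2.0 * x
        result = fit("LINE", error, Dataset(x, y))
        assert result.converged
        np.testing.assert_allclose(result.theta, [1.0, 2.0], atol=1e-6)
        assert result.sigma_hat == pytest.approx(0.0, abs=1e-7)

    def test_pow2_exact(self):
        x = np.geomspace(0.1, 5.0, 30)
        y = 0.7 * x**1.34
        result = fit("POW2", "lognormal", Dataset(x, y))
        np.testing.assert_allclose(result.theta, [0.7, 1.34], atol=1e-6)


class TestHuxlianEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_pow2_lognormal_equals_backtransformed_ols(self, seed):
        data = crab_like(seed)
        result = fit("POW2", "lognormal", data)
        b0, b1 = _loglog_ols(data.x, data.y)
        a_bt, b_bt = back_transform_loglinear(b0, b1)
        assert result.theta[0] == pytest.approx(a_bt, abs=1e-6)
        assert result.theta[1] == pytest.approx(b_bt, abs=1e-6)


def test_seeded_exponent_recovery():
    """POW2 truth (a=0.02, b=1.34, sigma=0.10, n=200, x in [0.05, 3])."""
    config = SimConfig(model="POW2", theta=(0.02, 1.34), sigma=0.10, n=200,
                       x_law="loguniform", x_min=0.05, x_max=3.0, seed=20240916)
    result = fit("POW2", "lognormal", generate(config))
    assert abs(result.theta[1] - 1.34) < 0.05


class TestFitPool:
    def test_pool_order_and_convergence(self):
        data = crab_like(4)
        results = fit_pool(["LINE0", "LINE", "POW2", "POW3"], "lognormal", data)
        assert [r.model for r in results] == ["LINE0", "LINE", "POW2", "POW3"]
        assert all(r.converged for r in results)

    def test_singleton_pool_equals_single_fit(self):
        data = crab_like(2)
        single = fit("POW2", "lognormal", data)
        (pooled,) = fit_pool(["POW2"], "lognormal", data)
        np.testing.assert_allclose(pooled.theta, single.theta, rtol=1e-12)
        assert pooled.loglik.value == pytest.approx(single.loglik.value)

    def test_duplicate_specs_are_deterministic(self):
        data = crab_like(3)
        r1, r2 = fit_pool(["POW2", "POW2"], "lognormal", data)
        np.testing.assert_array_equal(r1.theta, r2.theta)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_pool([], "lognormal", crab_like(1))


class TestOptimumQuality:
    @pytest.mark.parametrize("model", ["LINE", "POW2", "POW3", "SIG3"])
    def test_refit_from_optimum_does_not_improve(self, model):
        data = generate(SimConfig(model="POW3", theta=(2.0, 0.3, 1.3),
                                  sigma=0.1, n=120, seed=8))
        first = fit(model, "lognormal", data)
        again = fit(model, "lognormal", data, init=first.theta)
        assert again.loglik.value <= first.loglik.value + 1e-8

    def test_pow2_scale_equivariance(self):
        data = crab_like(6)
        base = fit("POW2", "lognormal", data)
        c = 3.7
        scaled = fit("POW2", "lognormal", Dataset(data.x, c * data.y))
        assert scaled.theta[0] == pytest.approx(c * base.theta[0], rel=1e-8)
        assert scaled.theta[1] == pytest.approx(base.theta[1], abs=1e-8)
        assert scaled.sigma_hat == pytest.approx(base.sigma_hat, abs=1e-8)


class TestProfileCI:
    def test_matches_gaussian_linear_closed_form(self):
        """For a Gaussian straight-line fit the profile interval for the
        slope has the closed form b +/- sqrt(SSE*(exp(c/n)-1)/Sxx)."""
        rng = np.random.default_rng(42)
        x = np.linspace(0, 10, 60)
        y = 1.5 + 0.8 * x + rng.normal(0, 0.5, 60)
        result = fit("LINE", "normal", Dataset(x, y))
        ci = profile_ci(result, "beta1", level=0.95)

        n = x.size
        slope, intercept = np.polyfit(x, y, 1)
        sse = float(np.sum((y - intercept - slope * x) ** 2))
        sxx = float(np.sum((x - x.mean()) ** 2))
        half = math.sqrt(sse * (math.exp(ci.cutoff / n) - 1.0) / sxx)
        assert ci.lower == pytest.approx(slope - half, rel=1e-3)
        assert ci.upper == pytest.approx(slope + half, rel=1e-3)

    def test_endpoints_sit_at_the_cutoff(self):
        data = crab_like(9)
        result = fit("POW2", "lognormal", data)
        ci = profile_ci(result, "b", level=0.95)
        j = result.spec.param_names.index("b")
        target = result.loglik.value - ci.cutoff / 2
        for bound in (ci.lower, ci.upper):
            assert _profile_loglik(result, j, bound) == pytest.approx(
                target, abs=1e-5)

    def test_interval_collapses_without_noise(self):
        x = np.linspace(1, 10, 30)
        result = fit("LINE", "normal", Dataset(x, 1.0 + 2.0 * x))
        ci = profile_ci(result, "beta1")
        assert ci.upper - ci.lower < 1e-4

    def test_contains_estimate_and_validates_input(self):
        result = fit("POW2", "lognormal", crab_like(5))
        ci = profile_ci(result, "b", level=0.95)
        assert ci.lower <= result.theta[1] <= ci.upper
        assert ci.cutoff == pytest.approx(3.841, abs=2e-3)
        with pytest.raises(KeyError, match="not a mean parameter"):
            profile_ci(result, "sigma")
        with pytest.raises(ValueError, match="level"):
            profile_ci(result, "b", level=1.5)


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        est = AllometricRegression(model="POW3", error="normal", n_restarts=2)
        cloned = clone(est)
        assert cloned.get_params()["model"] == "POW3"
        assert cloned.get_params()["n_restarts"] == 2

    def test_fit_predict_shapes(self):
        d = crab_like(1)
        est = AllometricRegression(model="POW2").fit(d.x.reshape(-1, 1), d.y)
        pred = est.predict(d.x.reshape(-1, 1))
        assert pred.shape == d.y.shape
        assert est.n_features_in_ == 1
        np.testing.assert_allclose(
            pred, evaluate_mean("POW2", est.theta_, d.x))

    def test_rejects_multicolumn_predictors(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="one predictor"):
            AllometricRegression().fit(X, np.ones(10))

    def test_smearing_requires_lognormal(self):
        x = np.linspace(1, 10, 20)
        est = AllometricRegression(model="LINE", error="normal").fit(
            x, 1 + 2 * x)
        with pytest.raises(ValueError, match="lognormal"):
            est.predict(x, smearing="parametric")
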