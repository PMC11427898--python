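"""Residual diagnostics, R-squared, and smearing corrections."""

import math

import numpy as np
import pytest

from allomfit.data import Dataset
from allomfit.diagnostics import (
    diagnose,
    normality_test,
    r_squared,
    smearing_correction,
    variance_test,
)
from allomfit.fitting import fit
from allomfit.models import evaluate_mean
from allomfit.synthdata import SimConfig, crab_like, generate


class TestVarianceTest:
    def test_null_calibration(self):
        """Homoscedastic Gaussian residuals reject near the nominal 5%."""
        rng = np.random.default_rng(101)
        rejections = 0
        reps = 200
        for _ in range(reps):
            x = rng.uniform(0, 10, 200)
            eps = rng.normal(0, 1, 200)
            rejections += not variance_test(eps, x).passed
        assert 0.01 <= rejections / reps <= 0.10

    def test_power_against_variance_growing_with_x(self):
        rng = np.random.default_rng(202)
        rejections = 0
        reps = 60
        for _ in range(reps):
            x = rng.uniform(0.5, 10, 200)
            eps = rng.normal(0, 1, 200) * x
            rejections += not variance_test(eps, x).passed
        assert rejections / reps >= 0.9

    def test_constant_residuals_degenerate(self):
        out = variance_test(np.zeros(20), np.linspace(1, 2, 20))
        assert out.degenerate

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="n >= 10"):
            variance_test(np.ones(5), np.ones(5))


class TestNormalityTest:
    def test_null_calibration(self):
        rng = np.random.default_rng(303)
        passes = sum(
            normality_test(rng.normal(size=100)).passed for _ in range(100)
        )
        assert passes >= 93

    def test_power_against_exponential(self):
        rng = np.random.default_rng(404)
        fails = sum(
            not normality_test(rng.exponential(size=100)).passed
            for _ in range(100)
        )
        assert fails >= 95

    def test_constant_residuals_degenerate(self):
        assert normality_test(np.full(30, 1.3)).degenerate

    def test_supported_range(self):
        with pytest.raises(ValueError):
            normality_test(np.ones(2))
        with pytest.raises(ValueError):
            normality_test(np.zeros(5001))

    def test_note_mentions_probability_statements(self):
        out = normality_test(np.random.default_rng(1).normal(size=50))
        assert "probability statements" in out.note


class TestRSquared:
    def test_perfect_fit_is_one(self):
        x = np.geomspace(0.5, 5, 20)
        result = fit("POW2", "lognormal", Dataset(x, 0.4 * x**1.2))
        assert r_squared(result) == pytest.approx(1.0, abs=1e-9)

    def test_origin_constraint_cannot_beat_free_intercept(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = 10.0 + 0.5 * x  # far offset from the origin
        r2_line = r_squared(fit("LINE", "normal", Dataset(x, y)))
        r2_line0 = r_squared(fit("LINE0", "normal", Dataset(x, y)))
        assert r2_line0 < r2_line

    def test_loglin_matches_ols_coefficient_of_determination(self):
        data = crab_like(12)
        result = fit("LOGLIN", "lognormal", data)
        lx, ly = np.log(data.x), np.log(data.y)
        oracle = float(np.corrcoef(lx, ly)[0, 1] ** 2)
        assert r_squared(result) == pytest.approx(oracle, abs=1e-12)


class TestSmearing:
    def test_parametric_factor_example(self):
        para, _ = smearing_correction(np.zeros(3), 0.2)
        assert para == pytest.approx(math.exp(0.02))

    def test_zero_residuals_give_unit_factors(self):
        assert smearing_correction(np.zeros(10), 0.0) == (1.0, 1.0)

    def test_factors_at_least_one_for_centered_residuals(self):
        rng = np.random.default_rng(7)
        eps = rng.normal(0, 0.3, 500)
        eps -= eps.mean()
        para, nonpara = smearing_correction(eps, float(np.std(eps)))
        assert para >= 1.0 and nonpara >= 1.0

    def test_corrected_predictions_match_arithmetic_means(self):
        """Monte-Carlo: at each x-bin the smeared prediction tracks the
        empirical arithmetic mean within 1% (sigma=0.3, n=10^4)."""
        sigma, n = 0.3, 10_000
        config = SimConfig(model="POW2", theta=(0.5, 1.3), sigma=sigma, n=n,
                           x_law="loguniform", x_min=0.5, x_max=8.0, seed=55)
        data = generate(config)
        result = fit("POW2", "lognormal", data)
        para, nonpara = smearing_correction(result.residual_vector,
                                            result.sigma_hat)
        edges = np.geomspace(0.5, 8.0, 5)
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (data.x >= lo) & (data.x < hi)
            empirical = data.y[mask].mean()
            corrected = (result.predict(data.x[mask]) * para).mean()
            assert corrected == pytest.approx(empirical, rel=0.03)
        assert nonpara == pytest.approx(para, rel=0.01)

    def test_parametric_and_nonparametric_agree_under_lognormality(self):
        rng = np.random.default_rng(88)
        sigma, n = 0.25, 2000
        eps = rng.normal(0, sigma, n)
        para, nonpara = smearing_correction(eps, float(np.sqrt(np.mean(eps**2))))
        se = float(np.std(np.exp(eps)) / math.sqrt(n))
        assert abs(nonpara - para) < 2 * se


def test_diagnose_bundle_for_lognormal_fit():
    data = crab_like(21)
    report = diagnose(fit("POW2", "lognormal", data))
    assert report.variance_test.method == "breusch-pagan"
    assert report.normality_test.method == "shapiro-wilk"
    assert 0 < report.r_squared <= 1
    assert report.smearing_parametric >= 1.0


def test_diagnose_omits_smearing_for_normal_error():
    x = np.linspace(1, 10, 40)
    y = 1 + 2 * x + np.random.default_rng(3).normal(0, 0.3, 40)
    report = diagnose(fit("LINE", "normal", Dataset(x, y)))
    assert report.smearing_parametric is None
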