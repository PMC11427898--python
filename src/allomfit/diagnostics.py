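"""Residual-assumption checks and fit-quality summaries.

After any fit the residuals (on the scale of the error structure: log
scale for lognormal, arithmetic for additive normal) are screened for
homoscedasticity with a Breusch–Pagan score test against the predictor
and for normality with the Shapiro–Wilk test. Both tests are advisory:
a normality failure affects probability statements (confidence
intervals, p-values) but not the parameter estimates themselves, and
the report text says so.

Also provided: R-squared on the residual scale of the fit, and the two
retransformation ("smearing") factors that convert a lognormal model's
predicted geometric means into arithmetic means — the parametric
exp(sigma_hat**2 / 2) and Duan's nonparametric mean(exp(residual)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "TestOutcome",
    "DiagnosticsReport",
    "variance_test",
    "normality_test",
    "r_squared",
    "smearing_correction",
    "diagnose",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TestOutcome:
    statistic: float
    p_value: float
    method: str
    passed: bool
    degenerate: bool = False
    note: str = ""


@dataclass(frozen=True)
class DiagnosticsReport:
    """Assumption checks and summaries for one fitted model."""

    variance_test: TestOutcome
    normality_test: TestOutcome
    r_squared: float
    r_squared_label: str
    smearing_parametric: float | None
    smearing_nonparametric: float | None
    alpha: float

    def to_dict(self) -> dict:
        return asdict(self)


def variance_test(residuals, x, alpha: float = DEFAULT_ALPHA) -> TestOutcome:
    """Breusch–Pagan score test of the residuals against the predictor.

    Regresses squared residuals on x; a small p-value indicates the
    residual variance drifts with the predictor (heteroscedasticity on
    the fitting scale).
    """
    residuals = np.asarray(residuals, dtype=float)
    x = np.asarray(x, dtype=float)
    if residuals.size != x.size:
        raise ValueError("residuals and x lengths differ")
    if residuals.size < 10:
        raise ValueError(f"variance test needs n >= 10, got {residuals.size}")
    if np.ptp(residuals) == 0:
        return TestOutcome(math.nan, math.nan, "breusch-pagan", False,
                           degenerate=True, note="constant residuals")
    exog = np.column_stack([np.ones_like(x), x])
    lm_stat, lm_p, _, _ = het_breuschpagan(residuals, exog)
    return TestOutcome(float(lm_stat), float(lm_p), "breusch-pagan",
                       passed=bool(lm_p >= alpha))


def normality_test(residuals, alpha: float = DEFAULT_ALPHA) -> TestOutcome:
    """Shapiro–Wilk test of the residual vector.

    Estimates are unaffected by a normality failure; only probability
    statements (intervals, p-values) are — the note records this.
    """
    residuals = np.asarray(residuals, dtype=float)
    if not 3 <= residuals.size <= 5000:
        raise ValueError(
            f"Shapiro-Wilk supported for 3 <= n <= 5000, got {residuals.size}"
        )
    if np.ptp(residuals) == 0:
        return TestOutcome(math.nan, math.nan, "shapiro-wilk", False,
                           degenerate=True, note="constant residuals")
    stat, p = stats.shapiro(residuals)
    return TestOutcome(
        float(stat), float(p), "shapiro-wilk", passed=bool(p >= alpha),
        note="a failure affects probability statements, not estimates",
    )


def r_squared(fitted) -> float:
    """Proportion of response variation explained, on the fitting scale.

    For lognormal error (and log-domain models) both SSE and the total
    sum of squares are taken on ln y; for additive normal error, on y.
    SST is about the mean of the response on that scale, so
    origin-constrained models can legitimately return negative values
    (reported, never clamped).
    """
    if not fitted.converged:
        raise ValueError("r_squared of a non-converged fit is meaningless")
    eps = np.asarray(fitted.residual_vector, dtype=float)
    y = np.asarray(fitted.y, dtype=float)
    scale_y = np.log(y) if fitted.structure.multiplicative else y
    sse = float(np.sum(eps**2))
    sst = float(np.sum((scale_y - scale_y.mean()) ** 2))
    if sst == 0:
        raise ZeroDivisionError("response is constant on the fitting scale")
    return 1.0 - sse / sst


def smearing_correction(residuals, sigma_hat: float) -> tuple[float, float]:
    """Geometric-to-arithmetic-mean retransformation factors.

    Returns ``(parametric, nonparametric)`` where parametric is
    exp(sigma_hat**2 / 2) and nonparametric is Duan's smearing estimate
    mean(exp(eps_i)). Residuals must be on the log scale (lognormal
    structure); multiply predictions by either factor to describe
    arithmetic rather than geometric means. The correction typically is
    minor and does not change the perceived pattern.
    """
    if sigma_hat < 0:
        raise ValueError("sigma_hat must be non-negative")
    residuals = np.asarray(residuals, dtype=float)
    parametric = math.exp(0.5 * sigma_hat**2)
    nonparametric = float(np.mean(np.exp(residuals)))
    return parametric, nonparametric


def diagnose(fitted, alpha: float = DEFAULT_ALPHA) -> DiagnosticsReport:
    """Full diagnostics bundle for one FitResult."""
    eps = fitted.residual_vector
    vt = variance_test(eps, fitted.x, alpha)
    nt = normality_test(eps, alpha)
    r2 = r_squared(fitted)
    label = ("R2 (log scale)" if fitted.structure.multiplicative else
             ("R2" if fitted.model in ("LINE", "LINE0") else "pseudo-R2"))
    if fitted.structure.multiplicative:
        para, nonpara = smearing_correction(eps, fitted.sigma_hat)
    else:
        para = nonpara = None
    return DiagnosticsReport(vt, nt, r2, label, para, nonpara, alpha)
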