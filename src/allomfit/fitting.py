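"""Maximum-likelihood fitting of allometric models.

The central object is :class:`AllometricRegression`, a scikit-learn style
estimator: choose a mean function from the pool and an error structure,
call ``fit(X, y)`` on untransformed measurements, and read off the
estimated parameters, the maximized log-likelihood, AICc and residuals.
Confidence intervals for individual mean parameters are computed by
profiling the likelihood (likelihood-ratio inversion), not from a
Wald/curvature approximation.

Estimation is full-information maximum likelihood with the scale
parameter concentrated out: for either error family the log-likelihood
at the ML sigma is a decreasing function of the residual sum of squares
(on the residual scale of the family), so the mean parameters are found
by trust-region least squares on the residual vector and
``sigma_hat = sqrt(mean(eps**2))`` follows in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import Dataset
from .errors import ErrorStructure, LogLikelihood, get_error_structure, log_likelihood
from .models import ModelSpec, get_model
from .selection import aicc

__all__ = [
    "FitResult",
    "ProfileCI",
    "AllometricRegression",
    "fit",
    "fit_pool",
    "profile_ci",
]

_PRED_FLOOR = 1e-12  # predictions below this are penalized under lognormal error


@dataclass(frozen=True)
class FitResult:
    """Outcome of one (model, error structure) maximum-likelihood fit."""

    spec: ModelSpec
    structure: ErrorStructure
    theta: np.ndarray
    sigma_hat: float
    loglik: LogLikelihood
    n: int
    k: int
    aicc: float
    converged: bool
    n_restarts_used: int
    residual_vector: np.ndarray
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def model(self) -> str:
        return self.spec.name

    @property
    def theta_dict(self) -> dict[str, float]:
        return dict(zip(self.spec.param_names, map(float, self.theta)))

    def predict(self, x) -> np.ndarray:
        from .models import evaluate_mean

        return evaluate_mean(self.spec, self.theta, x)


@dataclass(frozen=True)
class ProfileCI:
    """Likelihood-ratio confidence interval for one mean parameter.

    Bounds solve 2*(logL_max - logL_profile(theta_j)) = chi2_1(level),
    with every other parameter re-optimized at each trial value. An
    ``open`` flag marks a side where the drop was never bracketed (or a
    hard domain bound was reached first).
    """

    parameter: str
    level: float
    lower: float
    upper: float
    cutoff: float
    estimate: float
    lower_open: bool = False
    upper_open: bool = False

    def __post_init__(self) -> None:
        if not (self.lower <= self.estimate <= self.upper):
            raise ValueError("profile interval does not bracket the estimate")


# ---------------------------------------------------------------------------
# residual machinery


def _raw_residuals(spec, structure, x, y, theta):
    """Residual vector for least squares, with a smooth penalty pushing
    predictions back above zero when lognormal error demands positivity."""
    with np.errstate(all="ignore"):
        pred = np.asarray(spec.mean_function(x, theta), dtype=float)
    pred = np.nan_to_num(pred, nan=-1e30, posinf=1e30, neginf=-1e30)
    if structure.multiplicative:
        bad = pred < _PRED_FLOOR
        safe = np.where(bad, _PRED_FLOOR, pred)
        eps = np.log(y / safe)
        if np.any(bad):
            eps = eps + np.where(bad, 1e3 * (_PRED_FLOOR - pred), 0.0)
        return eps
    return y - pred


def _concentrated_loglik(structure, y, eps) -> float:
    """Log-likelihood at the ML sigma, from the residual sum of squares."""
    n = eps.size
    s2 = float(np.mean(eps**2))
    if s2 <= 0.0:
        return math.inf
    ll = -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)
    if structure.multiplicative:
        ll -= float(np.sum(np.log(y)))
    return ll


_LOG_CAP = 46.0  # strictly-positive params explored over (1e-20, 1e20)


def _solve(spec, structure, x, y, theta0, ftol, xtol, max_nfev):
    """Trust-region least squares on the residual vector.

    Strictly-positive parameters (lower bound at the positivity floor)
    are optimized on the log scale, which both enforces the constraint
    and flattens the K -> infinity ridge of sigmoids degenerating into
    power laws.
    """
    lower = np.asarray(spec.lower, dtype=float)
    upper = np.asarray(spec.upper, dtype=float)
    pos = (lower > 0) & ~np.isfinite(upper)
    theta0 = np.clip(np.asarray(theta0, dtype=float), lower, upper)

    def to_internal(theta):
        u = np.array(theta, dtype=float)
        u[pos] = np.log(np.clip(u[pos], 1e-20, 1e20))
        return u

    def to_external(u):
        theta = np.array(u, dtype=float)
        theta[pos] = np.exp(np.clip(theta[pos], -_LOG_CAP, _LOG_CAP))
        return theta

    lo_u = np.where(pos, -_LOG_CAP, lower)
    hi_u = np.where(pos, _LOG_CAP, upper)
    res = least_squares(
        lambda u: _raw_residuals(spec, structure, x, y, to_external(u)),
        np.clip(to_internal(theta0), lo_u, hi_u),
        bounds=(lo_u, hi_u),
        method="trf",
        ftol=ftol,
        xtol=xtol,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    res.x = to_external(res.x)
    return res


# ---------------------------------------------------------------------------
# the estimator


class AllometricRegression(RegressorMixin, BaseEstimator):
    """Single allometric model fitted by maximum likelihood.

    Parameters
    ----------
    model : str, default="POW2"
        Canonical pool identifier (LINE0, LINE, POW2, POW3, SIG3, SIG4,
        LOGLIN, LOGQUAD) or a :class:`~allomfit.models.ModelSpec`.
    error : str, default="lognormal"
        ``"lognormal"`` (multiplicative, heteroscedastic) or
        ``"normal"`` (additive, homoscedastic).
    init : sequence of float, optional
        User-supplied starting values; otherwise data-driven defaults
        (log-log OLS for power laws, OLS for lines, saturation
        heuristics for sigmoids).
    n_restarts : int, default=5
        Jittered restarts attempted when the first optimization fails
        to converge.
    restart_seed : int, default=20240916
        Seed for the restart jitter; fitting is deterministic.
    ftol, xtol : float
        Trust-region convergence tolerances on cost and parameters.
    max_nfev : int, default=10000
        Evaluation budget per optimizer run.

    Attributes
    ----------
    theta_ : ndarray
        Estimated mean parameters.
    sigma_ : float
        ML estimate of the error scale (log scale under lognormal).
    loglik_ : float
        Maximized log-likelihood on the original y scale.
    aicc_ : float
        Small-sample Akaike criterion with k = n_mean_params + 1.
    converged_ : bool
    residuals_ : ndarray
        Residuals at the optimum (``ln(obs/pred)`` under lognormal).
    result_ : FitResult
        The complete fit record consumed by selection/diagnostics.

    Examples
    --------
    >>> from allomfit import AllometricRegression
    >>> from allomfit.synthdata import crab_like
    >>> d = crab_like(seed=1)
    >>> est = AllometricRegression(model="POW2", error="lognormal").fit(d.x, d.y)
    >>> round(est.theta_[1], 2)  # allometric exponent (truth 1.34)
    1.39
    """

    def __init__(self, model="POW2", error="lognormal", init=None,
                 n_restarts=5, restart_seed=20240916,
                 ftol=1e-12, xtol=1e-12, max_nfev=10_000):
        self.model = model
        self.error = error
        self.init = init
        self.n_restarts = n_restarts
        self.restart_seed = restart_seed
        self.ftol = ftol
        self.xtol = xtol
        self.max_nfev = max_nfev

    # -- sklearn plumbing ---------------------------------------------------

    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        X = check_array(X, ensure_min_samples=3)
        if X.shape[1] != 1:
            raise ValueError(
                f"bivariate allometry takes exactly one predictor column, got {X.shape[1]}"
            )
        y = check_array(y, ensure_2d=False, ensure_min_samples=3).ravel()
        if y.size != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        return X, y

    def fit(self, X, y):
        """Fit the model to predictor X (n or n-by-1) and response y."""
        X, y = self._validate_xy(X, y)
        spec = self.model if isinstance(self.model, ModelSpec) else get_model(self.model)
        structure = get_error_structure(self.error)
        data = Dataset(X[:, 0], y)
        if structure.multiplicative or spec.domain == "logarithmic":
            data.require_positive()
        result = _fit_dataset(
            spec, structure, data,
            init=self.init, n_restarts=self.n_restarts,
            restart_seed=self.restart_seed, ftol=self.ftol, xtol=self.xtol,
            max_nfev=self.max_nfev,
        )
        self.n_features_in_ = 1
        self.result_ = result
        self.spec_ = spec
        self.structure_ = structure
        self.theta_ = result.theta
        self.param_names_ = spec.param_names
        self.sigma_ = result.sigma_hat
        self.loglik_ = result.loglik.value
        self.k_ = result.k
        self.n_ = result.n
        self.aicc_ = result.aicc
        self.converged_ = result.converged
        self.n_restarts_used_ = result.n_restarts_used
        self.residuals_ = result.residual_vector
        return self

    def predict(self, X, smearing=None):
        """Predicted response at X.

        Under lognormal error the raw prediction is a *geometric* mean;
        ``smearing="parametric"`` multiplies by exp(sigma_hat**2 / 2) and
        ``smearing="nonparametric"`` by Duan's mean(exp(residual)) to
        describe arithmetic means instead.
        """
        check_is_fitted(self, "result_")
        X = np.asarray(X, dtype=float)
        x1 = X[:, 0] if X.ndim == 2 else np.atleast_1d(X)
        pred = self.result_.predict(x1)
        if smearing is not None:
            from .diagnostics import smearing_correction

            if not self.structure_.multiplicative:
                raise ValueError("smearing applies only to lognormal-error fits")
            para, nonpara = smearing_correction(self.residuals_, self.sigma_)
            pred = pred * (para if smearing == "parametric" else nonpara)
        return pred

    def profile_ci(self, parameter, level=0.95, **kwargs) -> ProfileCI:
        """Likelihood-ratio confidence interval for one mean parameter."""
        check_is_fitted(self, "result_")
        return profile_ci(self.result_, parameter, level, **kwargs)


# ---------------------------------------------------------------------------
# core fitting routine (estimator internals; module functions wrap these)


def _fit_dataset(spec, structure, data, *, init=None, n_restarts=5,
                 restart_seed=20240916, ftol=1e-12, xtol=1e-12,
                 max_nfev=10_000, extra_starts=()) -> FitResult:
    x, y = data.x, data.y
    starts = ([np.asarray(init, dtype=float)] if init is not None
              else spec.initializer(x, y))
    starts = list(starts) + [np.asarray(s, dtype=float) for s in extra_starts]

    best = None
    for theta0 in starts:
        try:
            res = _solve(spec, structure, x, y, theta0, ftol, xtol, max_nfev)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    restarts_used = 0
    rng = np.random.default_rng(restart_seed)
    while (best is None or best.status <= 0) and restarts_used < n_restarts:
        base = starts[0]
        jitter = base * (1.0 + 0.25 * rng.standard_normal(base.size))
        jitter = jitter + 0.05 * rng.standard_normal(base.size)
        restarts_used += 1
        try:
            res = _solve(spec, structure, x, y, jitter, ftol, xtol, max_nfev)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        # every start failed outright: report a non-converged record at the
        # first start so the pool can carry on
        theta = np.clip(np.asarray(starts[0], dtype=float), spec.lower, spec.upper)
        converged = False
    else:
        # polish: re-run from the optimum so downstream refits cannot improve
        polished = _solve(spec, structure, x, y, best.x, ftol, xtol, max_nfev)
        best = polished if polished.cost <= best.cost else best
        theta = best.x
        converged = best.status > 0

    eps = _raw_residuals(spec, structure, x, y, theta)
    with np.errstate(all="ignore"):
        pred = np.asarray(spec.mean_function(x, theta), dtype=float)
    if structure.multiplicative and not np.all(pred > 0):
        converged = False

    s2 = float(np.mean(eps**2))
    sigma_hat = math.sqrt(s2)
    if sigma_hat > 0:
        ll = log_likelihood(structure, y, np.maximum(pred, _PRED_FLOOR)
                            if structure.multiplicative else pred, sigma_hat)
    else:  # exact interpolation: density degenerates
        ll = LogLikelihood(math.inf, np.full(y.size, math.inf), 0.0)

    k = spec.n_mean_params + 1  # sigma is an estimated parameter
    crit = aicc(ll.value, k, data.n) if data.n > k + 1 else math.inf
    return FitResult(
        spec=spec, structure=structure, theta=theta, sigma_hat=sigma_hat,
        loglik=ll, n=data.n, k=k, aicc=crit, converged=converged,
        n_restarts_used=restarts_used, residual_vector=eps, x=x, y=y,
    )


def fit(spec, structure, data: Dataset, init=None, **kwargs) -> FitResult:
    """Fit one model to a dataset by maximum likelihood.

    Thin wrapper over :class:`AllometricRegression`.
    """
    est = AllometricRegression(model=spec, error=structure, init=init, **kwargs)
    est.fit(data.x, data.y)
    return est.result_


_WARM_CHAIN = {  # extend a fitted simpler model into a start for the richer one
    "POW3": ("POW2", lambda t: np.concatenate([[0.0], t])),
    "SIG4": ("SIG3", lambda t: np.concatenate([[0.0], t])),
    "LOGQUAD": ("LOGLIN", lambda t: np.concatenate([t, [0.0]])),
    "LINE": ("LINE0", lambda t: np.concatenate([[0.0], t])),
}


def fit_pool(specs: Sequence, structure, data: Dataset, **kwargs) -> list[FitResult]:
    """Fit every model in a pool to the same dataset, order preserved.

    Nested models warm-start their richer extensions (a fitted POW2
    seeds POW3 with y0 = 0, and so on) in addition to the data-driven
    defaults, which stabilizes the multimodal three-parameter fits.
    """
    if not specs:
        raise ValueError("empty model pool")
    structure = get_error_structure(structure)
    fitted: dict[str, FitResult] = {}
    results = []
    for spec in specs:
        spec = spec if isinstance(spec, ModelSpec) else get_model(spec)
        extra = []
        chain = _WARM_CHAIN.get(spec.name)
        if chain and chain[0] in fitted and fitted[chain[0]].converged:
            extra.append(chain[1](fitted[chain[0]].theta))
        result = _fit_dataset(spec, structure, data, extra_starts=extra, **kwargs)
        fitted.setdefault(spec.name, result)
        results.append(result)
    return results


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


def _profile_loglik(result: FitResult, j: int, value: float,
                    ftol=1e-12, xtol=1e-12) -> float:
    """Log-likelihood maximized over all parameters except theta_j = value."""
    spec, structure = result.spec, result.structure
    x, y = result.x, result.y
    if spec.n_mean_params == 1:
        eps = _raw_residuals(spec, structure, x, y, np.array([value]))
        return _concentrated_loglik(structure, y, eps)
    keep = [i for i in range(spec.n_mean_params) if i != j]

    def reduced(t_red):
        full = np.empty(spec.n_mean_params)
        full[j] = value
        full[keep] = t_red
        return _raw_residuals(spec, structure, x, y, full)

    lo = np.asarray(spec.lower, dtype=float)[keep]
    hi = np.asarray(spec.upper, dtype=float)[keep]
    t0 = np.clip(result.theta[keep], lo, hi)
    res = least_squares(reduced, t0, bounds=(lo, hi), method="trf",
                        ftol=ftol, xtol=xtol, gtol=1e-12, max_nfev=5000)
    return _concentrated_loglik(structure, y, res.fun)


def profile_ci(result: FitResult, parameter: str, level: float = 0.95, *,
               ll_tol: float = 1e-6, max_doublings: int = 20) -> ProfileCI:
    """Invert the likelihood-ratio test for one mean parameter.

    Searches outward from the estimate, doubling the step until the
    profile log-likelihood drops below ``logL_max - chi2_1(level)/2``
    (at most ``max_doublings`` doublings, else the side is flagged
    open), then bisects the crossing to ``ll_tol`` in log-likelihood.
    """
    if not result.converged:
        raise ValueError("cannot profile a non-converged fit")
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    names = result.spec.param_names
    if parameter not in names:
        raise KeyError(f"{parameter!r} is not a mean parameter of {result.model}; "
                       f"choose from {names}")
    j = names.index(parameter)
    est = float(result.theta[j])
    cutoff = float(chi2.ppf(level, 1))
    ll_max = result.loglik.value
    if not math.isfinite(ll_max):  # perfect interpolation: interval collapses
        return ProfileCI(parameter, level, est, est, cutoff, est)
    target = ll_max - cutoff / 2.0

    lo_bound = float(result.spec.lower[j])
    hi_bound = float(result.spec.upper[j])
    step0 = max(abs(est), 1.0) * 0.01

    def search(direction: int) -> tuple[float, bool]:
        step, inner = step0, est
        for _ in range(max_doublings):
            cand = est + direction * step
            clipped = min(max(cand, lo_bound), hi_bound)
            ll = _profile_loglik(result, j, clipped)
            if ll < target:
                outer = clipped
                break
            inner = clipped
            if clipped != cand:  # pinned at a domain bound, still above target
                return clipped, True
            step *= 2.0
        else:
            return inner, True
        # bisect the crossing between inner (ll >= target) and outer
        for _ in range(200):
            mid = 0.5 * (inner + outer)
            ll = _profile_loglik(result, j, mid)
            if abs(ll - target) < ll_tol:
                return mid, False
            if ll >= target:
                inner = mid
            else:
                outer = mid
            if abs(outer - inner) <= 1e-14 * max(1.0, abs(est)):
                break
        return 0.5 * (inner + outer), False

    lower, lower_open = search(-1)
    upper, upper_open = search(+1)
    return ProfileCI(parameter, level, min(lower, est), max(upper, est),
                     cutoff, est, lower_open, upper_open)
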