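"""Two-segment (biphasic) log-linear regression with estimated breakpoint.

Biphasic allometry fits two straight lines to log-transformed data on
either side of a breakpoint tau on the ln x axis. It is provided here
mainly as a diagnostic foil: when the true arithmetic-scale relation
has a non-zero intercept, the log transform bends the distribution and
a piecewise fit "discovers" two growth phases that are artifacts of the
transformation — a single three-parameter power law on the original
scale then wins the AICc comparison.

The breakpoint is profiled over a deterministic grid: midpoints between
consecutive sorted unique ln x values leaving at least three points per
segment. Within segments the fit is ordinary least squares; requesting
``continuous=True`` constrains the segments to meet at tau (hinge
parameterization). The log-likelihood is reported on the original y
scale (lognormal error, shared sigma), so it is directly comparable
with arithmetic-domain pool fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import Dataset
from .selection import aicc as _aicc

__all__ = ["BiphasicFit", "fit_biphasic", "BiphasicLogRegression"]


@dataclass(frozen=True)
class BiphasicFit:
    """Fitted two-segment log-linear model."""

    tau: float
    left: tuple[float, float]  # (b0, b1) for ln x <= tau
    right: tuple[float, float]  # (b0, b1) for ln x > tau
    continuous: bool
    loglik: float
    k: int
    aicc: float
    n: int
    sigma_hat: float

    def predict_log(self, x) -> np.ndarray:
        lx = np.log(np.asarray(x, dtype=float))
        b0l, b1l = self.left
        b0r, b1r = self.right
        return np.where(lx <= self.tau, b0l + b1l * lx, b0r + b1r * lx)

    def predict(self, x) -> np.ndarray:
        return np.exp(self.predict_log(x))


def _segment_ols(lx, ly):
    X = np.column_stack([np.ones_like(lx), lx])
    beta, *_ = np.linalg.lstsq(X, ly, rcond=None)
    resid = ly - X @ beta
    return beta, float(resid @ resid)


def fit_biphasic(data: Dataset, continuous: bool = False,
                 min_per_segment: int = 3) -> BiphasicFit:
    """Profile the breakpoint over the interior ln x grid and fit segments.

    Parameters
    ----------
    data : Dataset
        Positive (x, y) pairs; n >= 7.
    continuous : bool, default False
        Constrain the two lines to meet at the breakpoint. The default
        (two free lines) mirrors the usual piecewise display.
    """
    data.require_positive()
    if data.n < 7:
        raise ValueError(f"biphasic fit needs n >= 7, got {data.n}")
    lx, ly = np.log(data.x), np.log(data.y)
    uniq = np.unique(lx)
    candidates = []
    for left_val, right_val in zip(uniq[:-1], uniq[1:]):
        tau = 0.5 * (left_val + right_val)
        if (np.sum(lx <= tau) >= min_per_segment
                and np.sum(lx > tau) >= min_per_segment):
            candidates.append(tau)
    if not candidates:
        raise ValueError(
            f"no breakpoint leaves {min_per_segment} points per segment"
        )

    best = None
    for tau in candidates:
        mask = lx <= tau
        if continuous:
            X = np.column_stack([np.ones_like(lx), lx, np.maximum(lx - tau, 0.0)])
            beta, *_ = np.linalg.lstsq(X, ly, rcond=None)
            resid = ly - X @ beta
            sse = float(resid @ resid)
            left = (float(beta[0]), float(beta[1]))
            right = (float(beta[0] - beta[2] * tau), float(beta[1] + beta[2]))
        else:
            bl, sse_l = _segment_ols(lx[mask], ly[mask])
            br, sse_r = _segment_ols(lx[~mask], ly[~mask])
            sse = sse_l + sse_r
            left = (float(bl[0]), float(bl[1]))
            right = (float(br[0]), float(br[1]))
        if best is None or sse < best[0]:
            best = (sse, tau, left, right)

    sse, tau, left, right = best
    n = data.n
    s2 = sse / n
    if s2 > 0:
        loglik = -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0) - float(np.sum(ly))
        sigma = math.sqrt(s2)
    else:
        loglik, sigma = math.inf, 0.0
    k = (3 if continuous else 4) + 1 + 1  # mean params + tau + sigma
    crit = _aicc(loglik, k, n) if n > k + 1 else math.inf
    return BiphasicFit(float(tau), left, right, continuous, loglik, k, crit,
                       n, sigma)


class BiphasicLogRegression(RegressorMixin, BaseEstimator):
    """Estimator wrapper around :func:`fit_biphasic`.

    Attributes after fitting: ``tau_``, ``left_``, ``right_``,
    ``loglik_``, ``aicc_``, ``k_``, ``fit_`` (the :class:`BiphasicFit`).
    """

    def __init__(self, continuous=False, min_per_segment=3):
        self.continuous = continuous
        self.min_per_segment = min_per_segment

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        x1 = X[:, 0] if X.ndim == 2 else X.ravel()
        result = fit_biphasic(Dataset(x1, np.asarray(y, dtype=float).ravel()),
                              continuous=self.continuous,
                              min_per_segment=self.min_per_segment)
        self.fit_ = result
        self.tau_ = result.tau
        self.left_ = result.left
        self.right_ = result.right
        self.loglik_ = result.loglik
        self.aicc_ = result.aicc
        self.k_ = result.k
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "fit_")
        X = np.asarray(X, dtype=float)
        x1 = X[:, 0] if X.ndim == 2 else np.atleast_1d(X)
        return self.fit_.predict(x1)
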