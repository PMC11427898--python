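"""Error structures and exact log-likelihoods.

Two error families are supported:

* ``lognormal`` — multiplicative, heteroscedastic: the residual is
  ``ln(observed / predicted)`` and the observation is lognormally
  distributed around the predicted *geometric* mean. The variance of y
  grows with its mean, the structure implicitly assumed whenever a
  straight line is fitted to log-transformed data.
* ``normal`` — additive, homoscedastic: the residual is
  ``observed - predicted`` with constant Gaussian scatter.

Likelihoods are always evaluated as densities of the observed y on its
original scale (the lognormal density carries a per-observation Jacobian
term ``-ln y``), so values are comparable across error families. Within
one family the Jacobian is a data constant and cancels from every
difference of AICc.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorStructure",
    "LOGNORMAL",
    "NORMAL",
    "get_error_structure",
    "LogLikelihood",
    "residuals",
    "log_likelihood",
    "profile_sigma",
    "DegenerateFitWarning",
]

_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateFitWarning(UserWarning):
    """Raised-as-warning when residuals are identically zero (sigma-hat = 0)."""


@dataclass(frozen=True)
class ErrorStructure:
    """Named residual rule plus per-observation density.

    ``lognormal`` requires strictly positive observations and predictions.
    """

    name: str
    multiplicative: bool

    def residuals(self, y_obs, y_pred) -> np.ndarray:
        y_obs = np.asarray(y_obs, dtype=float)
        y_pred = np.asarray(y_pred, dtype=float)
        if y_obs.shape != y_pred.shape:
            raise ValueError(
                f"length mismatch: {y_obs.shape} observed vs {y_pred.shape} predicted"
            )
        if self.multiplicative:
            for label, v in (("observed", y_obs), ("predicted", y_pred)):
                bad = np.flatnonzero(v <= 0)
                if bad.size:
                    raise ValueError(
                        f"lognormal error requires positive {label} values; "
                        f"row {bad[0]} has {v[bad[0]]:g}"
                    )
            return np.log(y_obs / y_pred)
        return y_obs - y_pred

    def per_obs_loglik(self, y_obs, y_pred, sigma: float) -> np.ndarray:
        if sigma <= 0:
            raise ValueError(f"sigma must be positive, got {sigma:g}")
        eps = self.residuals(y_obs, y_pred)
        core = -0.5 * _LOG_2PI - math.log(sigma) - eps**2 / (2.0 * sigma**2)
        if self.multiplicative:
            core = core - np.log(np.asarray(y_obs, dtype=float))
        return core


LOGNORMAL = ErrorStructure("lognormal", multiplicative=True)
NORMAL = ErrorStructure("normal", multiplicative=False)

_STRUCTURES = {"lognormal": LOGNORMAL, "normal": NORMAL,
               "lognormal_hetero": LOGNORMAL, "normal_homo": NORMAL}


def get_error_structure(name: str | ErrorStructure) -> ErrorStructure:
    if isinstance(name, ErrorStructure):
        return name
    try:
        return _STRUCTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown error structure {name!r}; choose 'lognormal' or 'normal'"
        ) from None


@dataclass(frozen=True)
class LogLikelihood:
    """Total log-likelihood on the original y scale, with its pieces."""

    value: float
    per_obs: np.ndarray
    sigma_hat: float

    def __post_init__(self) -> None:
        total = float(np.sum(self.per_obs))
        scale = max(1.0, abs(total))
        if not math.isclose(self.value, total, rel_tol=0, abs_tol=1e-9 * scale):
            raise ValueError("log-likelihood total inconsistent with per-obs terms")


def residuals(structure, y_obs, y_pred) -> np.ndarray:
    """Residual vector under the chosen error structure.

    ``ln(observed/predicted)`` for lognormal, ``observed - predicted``
    for additive normal.
    """
    return get_error_structure(structure).residuals(y_obs, y_pred)


def log_likelihood(structure, y_obs, y_pred, sigma: float) -> LogLikelihood:
    """Exact log-likelihood of the observations at scale ``sigma``."""
    structure = get_error_structure(structure)
    per_obs = structure.per_obs_loglik(y_obs, y_pred, sigma)
    return LogLikelihood(float(np.sum(per_obs)), per_obs, float(sigma))


def profile_sigma(structure, resid) -> float:
    """ML estimate of sigma for fixed mean parameters.

    The Gaussian likelihood in the residuals is maximized at
    sigma-hat = sqrt(mean(eps_i**2)) (concentrated ML, divisor n).
    Returns 0 with a :class:`DegenerateFitWarning` when every residual
    is exactly zero.
    """
    get_error_structure(structure)  # validates the name
    resid = np.asarray(resid, dtype=float)
    if resid.size < 2:
        raise ValueError("need at least 2 residuals to estimate sigma")
    s2 = float(np.mean(resid**2))
    if s2 == 0.0:
        warnings.warn("all residuals are zero; sigma-hat degenerate at 0",
                      DegenerateFitWarning, stacklevel=2)
        return 0.0
    return math.sqrt(s2)
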