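"""Candidate mean functions for bivariate allometry.

The fixed pool covers the functional forms routinely compared when a trait
is regressed on a body-size measure without transforming the data:

==========  =====================================  ==================
name        mean function                          parameters
==========  =====================================  ==================
``LINE0``   y = b1*x                               b1
``LINE``    y = b0 + b1*x                          b0, b1
``POW2``    y = a*x**b                             a, b
``POW3``    y = y0 + a*x**b                        y0, a, b
``SIG3``    y = A*x**h / (K**h + x**h)             A, K, h
``SIG4``    y = y0 + A*x**h / (K**h + x**h)        y0, A, K, h
``LOGLIN``  ln y = b0 + b1*ln x                    b0, b1
``LOGQUAD`` ln y = b0 + b1*ln x + b2*(ln x)**2     b0, b1, b2
==========  =====================================  ==================

Log-domain models evaluate to y = exp(polynomial in ln x) so that every
pool member maps x to an arithmetic-scale prediction; fitted with
lognormal error they reproduce ordinary least squares on the logs.

The three-parameter sigmoid is the Hill form: it passes through the
origin, is S-shaped on arithmetic axes for h > 1, and saturates at A.
Alternative sigmoid strategies (logistic, Gompertz, ...) can be swapped
in with :func:`register_model`.

All logarithms are natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "MODEL_POOL",
    "DEFAULT_ARITHMETIC_POOL",
    "DEFAULT_LOG_POOL",
    "get_model",
    "register_model",
    "evaluate_mean",
    "back_transform_loglinear",
    "forward_transform_power",
    "x_intercept",
]


@dataclass(frozen=True)
class ModelSpec:
    """A named mean function with domain constraints.

    Attributes
    ----------
    name : str
        Canonical identifier (``POW2``, ``SIG3``, ...).
    param_names : tuple of str
        Names of the mean parameters, in optimizer order.
    mean_function : callable
        ``(x, theta) -> y`` mapping, vectorized over x.
    domain : str
        ``"arithmetic"`` or ``"logarithmic"`` — the scale on which the
        functional form is naturally expressed. Log-domain models still
        return arithmetic-scale predictions.
    lower, upper : tuple of float
        Per-parameter box constraints (``-inf``/``inf`` when free).
    initializer : callable
        ``(x, y) -> list of theta`` candidate starting points.
    """

    name: str
    param_names: tuple[str, ...]
    mean_function: Callable[[np.ndarray, np.ndarray], np.ndarray]
    domain: str = "arithmetic"
    lower: tuple[float, ...] = ()
    upper: tuple[float, ...] = ()
    initializer: Callable[[np.ndarray, np.ndarray], list[np.ndarray]] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        k = len(self.param_names)
        if not self.lower:
            object.__setattr__(self, "lower", (-np.inf,) * k)
        if not self.upper:
            object.__setattr__(self, "upper", (np.inf,) * k)
        if len(self.lower) != k or len(self.upper) != k:
            raise ValueError(f"bounds length mismatch for {self.name}")

    @property
    def n_mean_params(self) -> int:
        return len(self.param_names)

    def __call__(self, x, theta):
        return evaluate_mean(self, theta, x)


def evaluate_mean(spec: ModelSpec | str, theta: Sequence[float], x) -> np.ndarray:
    """Evaluate a pool mean function at ``x``.

    Raises
    ------
    ValueError
        If the prediction is non-finite anywhere, naming the offending
        x value and parameter vector.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    theta = np.asarray(theta, dtype=float)
    if theta.size != spec.n_mean_params:
        raise ValueError(
            f"{spec.name} expects {spec.n_mean_params} parameters, got {theta.size}"
        )
    x_arr = np.asarray(x, dtype=float)
    with np.errstate(all="ignore"):
        y = np.asarray(spec.mean_function(np.atleast_1d(x_arr), theta), dtype=float)
    if not np.all(np.isfinite(y)):
        bad = np.flatnonzero(~np.isfinite(y))[0]
        raise ValueError(
            f"{spec.name} produced non-finite prediction at "
            f"x={np.atleast_1d(x_arr)[bad]:g} with theta={theta.tolist()}"
        )
    return y if x_arr.ndim else float(y[0])


# ---------------------------------------------------------------------------
# transforms between the Huxlian log-line and the power equation


def back_transform_loglinear(b0: float, b1: float) -> tuple[float, float]:
    """Exponentiate a log-log straight line into power-law parameters.

    ln y = b0 + b1*ln x  becomes  y = a*x**b with a = exp(b0), b = b1.
    """
    if not (math.isfinite(b0) and math.isfinite(b1)):
        raise ValueError("log-line parameters must be finite")
    return math.exp(b0), b1


def forward_transform_power(a: float, b: float) -> tuple[float, float]:
    """Log-transform a power law into its log-log straight line.

    Exact inverse of :func:`back_transform_loglinear`.
    """
    if a <= 0:
        raise ValueError(f"power coefficient must be positive, got a={a:g}")
    return math.log(a), b


def x_intercept(beta0: float, beta1: float) -> float:
    """X-axis crossing of the straight line y = beta0 + beta1*x."""
    if beta1 == 0:
        raise ZeroDivisionError("horizontal line has no X-intercept")
    return -beta0 / beta1


# ---------------------------------------------------------------------------
# initializers (deterministic, data-driven starting values)


def _ols_line(x, y, through_origin=False):
    if through_origin:
        return np.array([float(np.dot(x, y) / np.dot(x, x))])
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _loglog_ols(x, y, degree=1):
    lx, ly = np.log(np.clip(x, 1e-300, None)), np.log(np.clip(y, 1e-300, None))
    X = np.column_stack([lx**d for d in range(degree + 1)])
    beta, *_ = np.linalg.lstsq(X, ly, rcond=None)
    return beta


def _init_line0(x, y):
    return [_ols_line(x, y, through_origin=True)]


def _init_line(x, y):
    return [_ols_line(x, y)]


def _init_pow2(x, y):
    b0, b1 = _loglog_ols(x, y)
    return [np.array([math.exp(b0), b1])]


def _init_pow3(x, y):
    starts = []
    for y0 in (0.0, float(np.min(y)) / 2.0):
        shifted = y - y0
        if np.all(shifted > 0):
            b0, b1 = _loglog_ols(x, shifted)
            starts.append(np.array([y0, math.exp(b0), b1]))
    if not starts:  # responses straddle the trial intercepts
        b0, b1 = _loglog_ols(x, np.abs(y) + 1e-12)
        starts.append(np.array([0.0, math.exp(b0), b1]))
    return starts


def _init_sig3(x, y):
    # saturating start, plus a near-linear start (K far above the data,
    # h = 1) for samples with no visible plateau
    slope = float(np.dot(x, y) / np.dot(x, x))
    k_far = 10.0 * float(np.max(x))
    return [
        np.array([1.2 * float(np.max(y)), float(np.median(x)), 2.0]),
        np.array([slope * k_far, k_far, 1.0]),
    ]


def _init_sig4(x, y):
    return [np.concatenate([[0.0], _init_sig3(x, y)[0]])]


def _init_loglin(x, y):
    return [_loglog_ols(x, y)]


def _init_logquad(x, y):
    return [_loglog_ols(x, y, degree=2)]


# ---------------------------------------------------------------------------
# the pool


def _f_line0(x, t):
    return t[0] * x


def _f_line(x, t):
    return t[0] + t[1] * x


def _f_pow2(x, t):
    return t[0] * np.power(x, t[1])


def _f_pow3(x, t):
    return t[0] + t[1] * np.power(x, t[2])


def _f_sig3(x, t):
    A, K, h = t
    xh = np.power(x, h)
    return A * xh / (np.power(K, h) + xh)


def _f_sig4(x, t):
    return t[0] + _f_sig3(x, t[1:])


def _f_loglin(x, t):
    return np.exp(t[0] + t[1] * np.log(x))


def _f_logquad(x, t):
    lx = np.log(x)
    return np.exp(t[0] + t[1] * lx + t[2] * lx * lx)


_POS = 1e-12  # open lower bound for strictly positive parameters

MODEL_POOL: dict[str, ModelSpec] = {}


def register_model(spec: ModelSpec, overwrite: bool = False) -> None:
    """Add a model (e.g. an alternative sigmoid strategy) to the pool."""
    if spec.name in MODEL_POOL and not overwrite:
        raise ValueError(f"model {spec.name!r} already registered")
    MODEL_POOL[spec.name] = spec


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_POOL[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; choose from {sorted(MODEL_POOL)}"
        ) from None


for _spec in [
    ModelSpec("LINE0", ("beta1",), _f_line0, initializer=_init_line0,
              description="straight line through the origin"),
    ModelSpec("LINE", ("beta0", "beta1"), _f_line, initializer=_init_line,
              description="straight line with explicit intercept"),
    ModelSpec("POW2", ("a", "b"), _f_pow2, lower=(_POS, -np.inf),
              initializer=_init_pow2,
              description="two-parameter power equation (simple allometry)"),
    ModelSpec("POW3", ("y0", "a", "b"), _f_pow3,
              lower=(-np.inf, _POS, -np.inf), initializer=_init_pow3,
              description="three-parameter power equation (non-zero intercept)"),
    ModelSpec("SIG3", ("A", "K", "h"), _f_sig3,
              lower=(_POS, _POS, _POS), initializer=_init_sig3,
              description="three-parameter Hill sigmoid through the origin"),
    ModelSpec("SIG4", ("y0", "A", "K", "h"), _f_sig4,
              lower=(-np.inf, _POS, _POS, _POS), initializer=_init_sig4,
              description="Hill sigmoid plus additive intercept"),
    ModelSpec("LOGLIN", ("b0", "b1"), _f_loglin, domain="logarithmic",
              initializer=_init_loglin,
              description="straight line on the log-log scale"),
    ModelSpec("LOGQUAD", ("b0", "b1", "b2"), _f_logquad, domain="logarithmic",
              initializer=_init_logquad,
              description="quadratic on the log-log scale (complex allometry)"),
]:
    register_model(_spec)

DEFAULT_ARITHMETIC_POOL = ("LINE0", "LINE", "POW2", "POW3", "SIG3", "SIG4")
DEFAULT_LOG_POOL = ("LOGLIN", "LOGQUAD")
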