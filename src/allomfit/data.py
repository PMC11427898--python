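"""Bivariate dataset container for allometric analyses.

A dataset is a pair of positive measurement vectors: a body-size predictor
(body mass, interantennal distance, ...) and a trait response (claw mass,
flange width, ...). Positivity is required whenever a lognormal error
structure or a log-domain model is in play; plain additive-normal fits
tolerate non-positive responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Dataset:
    """Paired positive observations (x_i, y_i), the unit of analysis.

    Parameters
    ----------
    x : array-like
        Predictor values (e.g. body mass in g). Must be finite.
    y : array-like
        Response values (e.g. claw mass in g). Must be finite.
    labels : tuple of str, optional
        Column names, used in reports.
    """

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, str] = field(default=("x", "y"))

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError(f"x and y lengths differ: {x.size} != {y.size}")
        if x.size < 3:
            raise ValueError(f"need at least 3 observations, got {x.size}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in dataset")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    def require_positive(self) -> None:
        """Raise unless every x and y is strictly positive.

        Called before any lognormal-error or log-domain computation.
        """
        for name, v in ((self.labels[0], self.x), (self.labels[1], self.y)):
            bad = np.flatnonzero(v <= 0)
            if bad.size:
                raise ValueError(
                    f"column {name!r} has non-positive value {v[bad[0]]:g} "
                    f"at row {bad[0]}; lognormal/log-domain analyses require "
                    "strictly positive data"
                )

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n
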