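"""Information-criterion model comparison.

Candidate fits are ranked by AICc, Akaike's criterion with the
small-sample correction::

    AICc = -2*logL + 2k + 2k(k+1)/(n - k - 1)

with k counting the error scale sigma alongside the mean parameters.
Models whose AICc exceeds the best by less than a consideration
threshold (default 7) are flagged "worthy of consideration"; a richer
model sitting within 2 AICc of a nested simpler one earns an advisory
overfitting note (the two capture virtually identical information, so
the extra parameter buys nothing). Akaike weights are reported for
convenience but never drive elimination.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["aicc", "akaike_weights", "compare", "ComparisonRow", "ComparisonTable",
           "DEFAULT_THRESHOLD", "NESTED_SIMPLER"]

DEFAULT_THRESHOLD = 7.0
_OVERFIT_MARGIN = 2.0

# simpler models nested inside each pool member (used for overfitting notes)
NESTED_SIMPLER = {
    "LINE": ("LINE0",),
    "POW2": ("LINE0",),
    "POW3": ("POW2", "LINE"),
    "SIG4": ("SIG3",),
    "LOGQUAD": ("LOGLIN",),
}


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(
            f"AICc correction undefined for n={n}, k={k} (need n > k + 1)"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(delta: np.ndarray) -> np.ndarray:
    """Normalized evidence weights exp(-delta/2) / sum."""
    delta = np.asarray(delta, dtype=float)
    w = np.exp(-0.5 * (delta - np.min(delta)))
    return w / np.sum(w)


@dataclass(frozen=True)
class ComparisonRow:
    model: str
    k: int
    loglik: float
    aicc: float
    delta_aicc: float
    weight: float
    considered: bool
    converged: bool
    note: str = ""


@dataclass(frozen=True)
class ComparisonTable:
    """Per-model AICc ranking for one fitted pool."""

    rows: tuple[ComparisonRow, ...]
    best: str
    threshold: float
    n: int

    def row(self, model: str) -> ComparisonRow:
        for r in self.rows:
            if r.model == model:
                return r
        raise KeyError(model)

    def to_dict(self) -> dict:
        return {
            "best": self.best,
            "threshold": self.threshold,
            "n": self.n,
            "rows": [vars(r) for r in self.rows],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        """Aligned plain-text table in the layout of a model-selection report."""
        header = f"{'model':<9}{'k':>3}{'logL':>12}{'AICc':>12}{'dAICc':>9}{'weight':>8}  {'flag':<12}note"
        lines = [header, "-" * len(header)]
        for r in self.rows:
            flag = "considered" if r.considered else (
                "non-conv" if not r.converged else "dismissed")
            lines.append(
                f"{r.model:<9}{r.k:>3}{r.loglik:>12.4g}{r.aicc:>12.4g}"
                f"{r.delta_aicc:>9.4g}{r.weight:>8.3f}  {flag:<12}{r.note}"
            )
        return "\n".join(lines)


def compare(results, threshold: float = DEFAULT_THRESHOLD) -> ComparisonTable:
    """Rank a fitted pool by AICc and apply the elimination logic.

    Non-converged fits are carried in the table (flagged, never "best");
    rows are sorted by AICc ascending with ties broken by smaller k,
    then pool order. ``considered`` means converged and
    ``delta_AICc < threshold``.
    """
    results = list(results)
    if not results:
        raise ValueError("no fits to compare")
    ns = {r.n for r in results}
    if len(ns) != 1:
        raise ValueError(f"fits come from datasets of different sizes: {sorted(ns)}")
    converged = [r for r in results if r.converged and math.isfinite(r.aicc)]
    if not converged:
        raise ValueError("no converged fit in the pool")

    best_aicc = min(r.aicc for r in converged)
    order = sorted(range(len(results)),
                   key=lambda i: (results[i].aicc, results[i].k, i))
    deltas = np.array([results[i].aicc - best_aicc for i in order])
    ok = np.array([results[i].converged for i in order])
    weights = np.where(ok, akaike_weights(np.where(ok, deltas, np.inf)), 0.0)
    # renormalize over converged rows only
    if weights.sum() > 0:
        weights = weights / weights.sum()

    by_name = {r.model: r for r in results}
    rows = []
    best_name = None
    for pos, i in enumerate(order):
        r = results[i]
        delta = float(r.aicc - best_aicc)
        notes = []
        if not r.converged:
            notes.append("did not converge; excluded from ranking")
        else:
            if best_name is None:
                best_name = r.model
            for simpler in NESTED_SIMPLER.get(r.model, ()):
                sr = by_name.get(simpler)
                # the extra parameter must buy a clear AICc advantage,
                # otherwise the richer model is flagged as overfitted
                if (sr is not None and sr.converged and r.k > sr.k
                        and sr.aicc - r.aicc < _OVERFIT_MARGIN):
                    notes.append(
                        f"no clear AICc gain over nested {simpler}: "
                        "possible overfitting"
                    )
        rows.append(ComparisonRow(
            model=r.model, k=r.k, loglik=float(r.loglik.value),
            aicc=float(r.aicc), delta_aicc=delta, weight=float(weights[pos]),
            considered=bool(r.converged and delta < threshold),
            converged=bool(r.converged), note="; ".join(notes),
        ))
    return ComparisonTable(tuple(rows), best_name, float(threshold),
                           int(next(iter(ns))))
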