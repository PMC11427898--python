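"""Dataset readers, analysis configuration, and report assembly.

`run_analysis` ties the whole protocol together: read a CSV/TSV of
paired measurements, fit the requested model pool by maximum
likelihood, rank by AICc, run residual diagnostics and profile
confidence intervals for every considered model, and emit a JSON report
plus an aligned plain-text table. Reports carry no timestamps, so
re-running on the same inputs reproduces the JSON byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .data import Dataset
from .diagnostics import DEFAULT_ALPHA, diagnose
from .fitting import fit_pool, profile_ci
from .models import MODEL_POOL, x_intercept
from .piecewise import fit_biphasic
from .selection import DEFAULT_THRESHOLD, compare

__all__ = ["read_dataset", "AnalysisConfig", "run_analysis", "write_report"]

logger = logging.getLogger("allomfit")

DEFAULT_MODELS = ("LINE0", "LINE", "POW2", "POW3")


def read_dataset(path, x_col: str, y_col: str,
                 require_positive: bool = True) -> Dataset:
    """Read paired measurements from a delimited text file.

    The delimiter is sniffed among comma, tab and semicolon; lines
    starting with ``#`` are comments. Rows with missing values are
    dropped with a logged count; rows with non-positive values are
    dropped (and logged) only when a lognormal or log-domain analysis
    is requested via ``require_positive``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     skip_blank_lines=True)
    for col in (x_col, y_col):
        if col not in df.columns:
            raise KeyError(
                f"column {col!r} not found in {path.name}; "
                f"available: {list(df.columns)}"
            )
    sub = df[[x_col, y_col]].copy()
    for col in (x_col, y_col):
        raw = sub[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {raw.iloc[row]!r} in column {col!r} "
                f"at data row {row}"
            )
        sub[col] = num
    n_total = len(sub)
    sub = sub.dropna()
    n_missing = n_total - len(sub)
    if n_missing:
        logger.warning("dropped %d row(s) with missing values", n_missing)
    if require_positive:
        keep = (sub[x_col] > 0) & (sub[y_col] > 0)
        n_nonpos = int((~keep).sum())
        if n_nonpos:
            logger.warning("dropped %d row(s) with non-positive values "
                           "(lognormal/log-domain analysis)", n_nonpos)
        sub = sub[keep]
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 usable rows in {path.name}")
    return Dataset(sub[x_col].to_numpy(float), sub[y_col].to_numpy(float),
                   labels=(x_col, y_col))


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to run the protocol once."""

    input: str | None = None
    x_col: str = "x"
    y_col: str = "y"
    models: tuple[str, ...] = DEFAULT_MODELS
    error: str = "lognormal"
    threshold: float = DEFAULT_THRESHOLD
    ci_level: float = 0.95
    alpha: float = DEFAULT_ALPHA
    output: str | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model list must not be empty")
        for m in self.models:
            if m != "BIPHASIC" and m not in MODEL_POOL:
                raise ValueError(f"unknown model {m!r}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


def _fit_to_dict(result) -> dict:
    return {
        "model": result.model,
        "params": result.theta_dict,
        "sigma_hat": float(result.sigma_hat),
        "loglik": float(result.loglik.value),
        "k": int(result.k),
        "n": int(result.n),
        "aicc": float(result.aicc),
        "converged": bool(result.converged),
        "n_restarts_used": int(result.n_restarts_used),
    }


def run_analysis(config: AnalysisConfig, data: Dataset | None = None):
    """Execute read -> fit pool -> compare -> diagnostics -> profile CIs.

    Returns ``(report_dict, text_table)``; writes them to
    ``config.output`` (JSON) and ``config.output + '.txt'`` when an
    output path is configured.
    """
    if data is None:
        if config.input is None:
            raise ValueError("either a dataset or an input path is required")
        data = read_dataset(config.input, config.x_col, config.y_col,
                            require_positive=config.error == "lognormal")
    pool_names = [m for m in config.models if m != "BIPHASIC"]
    results = fit_pool(pool_names, config.error, data)
    rows = list(results)
    if "BIPHASIC" in config.models:
        bi = fit_biphasic(data)
        rows.append(SimpleNamespace(
            model="BIPHASIC", k=bi.k, n=bi.n, aicc=bi.aicc, converged=True,
            loglik=SimpleNamespace(value=bi.loglik),
        ))
    table = compare(rows, threshold=config.threshold)

    models_out = {}
    for result in results:
        entry = _fit_to_dict(result)
        row = table.row(result.model)
        entry["delta_aicc"] = row.delta_aicc
        entry["considered"] = row.considered
        entry["note"] = row.note
        if result.converged:
            entry["diagnostics"] = diagnose(result, alpha=config.alpha).to_dict()
            if result.model == "LINE" and result.theta[1] != 0:
                entry["x_intercept"] = float(x_intercept(*result.theta))
            if row.considered:
                cis = {}
                for name in result.spec.param_names:
                    ci = profile_ci(result, name, level=config.ci_level)
                    cis[name] = {
                        "lower": ci.lower, "upper": ci.upper,
                        "level": ci.level, "cutoff": ci.cutoff,
                        "lower_open": ci.lower_open, "upper_open": ci.upper_open,
                    }
                entry["profile_ci"] = cis
        models_out[result.model] = entry

    report = {
        "dataset": {
            "n": int(data.n),
            "x_label": data.labels[0],
            "y_label": data.labels[1],
            "source": config.input,
        },
        "error_structure": config.error,
        "residual_convention": "ln(observed/predicted)"
        if config.error == "lognormal" else "observed - predicted",
        "k_convention": "mean parameters + 1 (sigma counted)",
        "threshold": config.threshold,
        "comparison": table.to_dict(),
        "models": models_out,
    }
    text = table.to_text()
    if config.output:
        write_report(report, text, config.output)
    return report, text


def write_report(report: dict, text: str, path) -> None:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    path.with_suffix(path.suffix + ".txt").write_text(text + "\n")
    logger.info("report written to %s", path)
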