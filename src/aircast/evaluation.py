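"""Forecast accuracy metrics and comparison arithmetic.

Two coefficients of determination are reported side by side: the
explained-variance ratio sum((f - ybar)^2) / sum((y - ybar)^2) used in the
source methodology ("paper" form), and the conventional 1 - SSE/SST.  The
two agree when predictions are an orthogonal projection of y (e.g. an OLS
fit) but can differ otherwise; the conventional form is used for ranking
and the other is printed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    mae: float
    r2_paper: float
    r2_conventional: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "r2_paper": self.r2_paper,
            "r2_conventional": self.r2_conventional,
            "n": self.n,
        }


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true, dtype=float).ravel()
    f = np.asarray(y_pred, dtype=float).ravel()
    if len(y) != len(f):
        raise ValueError(f"length mismatch: y_true has {len(y)}, y_pred has {len(f)}")
    if len(y) == 0:
        raise ValueError("empty inputs")
    return y, f


def rmse(y_true, y_pred) -> float:
    """Root mean squared error sqrt(mean((y - f)^2))."""
    y, f = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((y - f) ** 2)))


def mae(y_true, y_pred) -> float:
    """Mean absolute error mean(|f - y|)."""
    y, f = _check_pair(y_true, y_pred)
    return float(np.mean(np.abs(f - y)))


def r2(y_true, y_pred, form: str = "conventional") -> float:
    """Coefficient of determination in either form (see module docstring)."""
    y, f = _check_pair(y_true, y_pred)
    ybar = y.mean()
    sst = float(np.sum((y - ybar) ** 2))
    if sst == 0.0:
        raise ValueError("y_true is constant; R^2 undefined (zero denominator)")
    if form == "paper":
        return float(np.sum((f - ybar) ** 2)) / sst
    if form == "conventional":
        return 1.0 - float(np.sum((y - f) ** 2)) / sst
    raise ValueError(f"unknown form {form!r}; expected 'paper' or 'conventional'")


def metrics_report(y_true, y_pred) -> MetricsReport:
    """Bundle all metrics; R^2 fields are NaN when y_true is constant
    (the ratio forms are undefined there, but RMSE/MAE still apply)."""
    y, f = _check_pair(y_true, y_pred)
    if np.ptp(y) == 0.0:
        r2p = r2c = float("nan")
    else:
        r2p = r2(y, f, "paper")
        r2c = r2(y, f, "conventional")
    return MetricsReport(rmse=rmse(y, f), mae=mae(y, f), r2_paper=r2p, r2_conventional=r2c, n=len(y))


def percent_reduction(before: float, after: float) -> float:
    """100 * (before - after) / before — the improvement of *after* over
    *before* as a percentage of *before*."""
    if before <= 0:
        raise ValueError("before must be positive")
    return 100.0 * (before - after) / before


def comparison_report(results: list[tuple[str, MetricsReport]]) -> dict[str, pd.DataFrame]:
    """Per-model metric table plus pairwise reductions / R^2 differences.

    Returns ``{"metrics": ..., "pairwise": ...}``; the pairwise table has
    one row per ordered pair (baseline, candidate) following the input
    order, with RMSE/MAE percent reductions and R^2 gains of the candidate
    relative to the baseline.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    labels = [lab for lab, _ in results]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate model labels")
    metrics = pd.DataFrame(
        [
            {
                "model": lab,
                "rmse": rep.rmse,
                "mae": rep.mae,
                "r2": rep.r2_conventional,
                "r2_paper": rep.r2_paper,
            }
            for lab, rep in results
        ]
    ).set_index("model")
    rows = []
    for i, (lab_a, a) in enumerate(results):
        for lab_b, b in results[i + 1:]:
            rows.append(
                {
                    "baseline": lab_a,
                    "candidate": lab_b,
                    "rmse_reduction_pct": round(percent_reduction(a.rmse, b.rmse), 2),
                    "mae_reduction_pct": round(percent_reduction(a.mae, b.mae), 2),
                    "r2_gain": b.r2_conventional - a.r2_conventional,
                }
            )
    return {"metrics": metrics, "pairwise": pd.DataFrame(rows)}
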