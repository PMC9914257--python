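"""Fit-quality metrics and polynomial-order selection.

R-squared measures the fraction of moisture-ratio variance explained;
the adjusted variant penalises the Q = n + 1 estimated coefficients so
that models of different order are comparable, and the order with the
largest adjusted R-squared wins (ties go to the smaller order, then to
the smaller RMSE).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError

__all__ = [
    "FitMetrics",
    "r_squared",
    "adjusted_r_squared",
    "rmse",
    "compute_metrics",
    "select_order",
    "metrics_table",
]


@dataclass(frozen=True)
class FitMetrics:
    r2: float
    adj_r2: float
    rmse: float
    d: int
    n: int

    def as_dict(self) -> dict:
        return {
            "R2": self.r2,
            "adjR2": self.adj_r2,
            "RMSE": self.rmse,
            "D": self.d,
            "n": self.n,
        }


def r_squared(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSE/SST about the observed mean."""
    pred = np.asarray(predicted, dtype=np.float64)
    obs = np.asarray(observed, dtype=np.float64)
    if pred.shape != obs.shape or pred.size == 0:
        raise DataError("predicted and observed must be non-empty and of equal length")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise DataError("observed values are all equal: R^2 undefined")
    sse = float(np.sum((pred - obs) ** 2))
    return 1.0 - sse / sst


def adjusted_r_squared(r2: float, d: int, n: int) -> float:
    """Adjust R^2 for the n + 1 estimated coefficients:
    ``1 - (1 - R^2)(D - 1) / (D - (n + 1))``."""
    if d <= n + 1:
        raise DataError(
            f"adjusted R^2 needs D > n + 1 (got D={d}, n={n})"
        )
    return 1.0 - (1.0 - r2) * (d - 1) / (d - (n + 1))


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root-mean-square prediction error."""
    pred = np.asarray(predicted, dtype=np.float64)
    obs = np.asarray(observed, dtype=np.float64)
    if pred.shape != obs.shape or pred.size == 0:
        raise DataError("predicted and observed must be non-empty and of equal length")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def compute_metrics(
    predicted: Sequence[float], observed: Sequence[float], n: int
) -> FitMetrics:
    """Bundle R^2, adjusted R^2 and RMSE for an order-``n`` fit."""
    obs = np.asarray(observed, dtype=np.float64)
    r2 = r_squared(predicted, obs)
    return FitMetrics(
        r2=r2,
        adj_r2=adjusted_r_squared(r2, obs.size, n),
        rmse=rmse(predicted, obs),
        d=int(obs.size),
        n=n,
    )


def select_order(candidate_fits: Sequence[tuple[int, FitMetrics]]) -> int:
    """Pick the order with maximal adjusted R^2.

    Ties are broken by the smaller order (parsimony) and then by the
    smaller RMSE.
    """
    if not candidate_fits:
        raise DataError("no candidate fits to select from")
    best = min(candidate_fits, key=lambda c: (-c[1].adj_r2, c[0], c[1].rmse))
    return int(best[0])


def metrics_table(candidate_fits: Sequence[tuple[int, FitMetrics, Sequence[float]]]) -> str:
    """Plain-text report: one row per order with coefficients and metrics,
    rounded to 4 decimal places."""
    lines = ["n  coefficients                                    R2      adjR2   RMSE"]
    for n, m, coeffs in candidate_fits:
        cstr = ", ".join(f"{c:.4f}" for c in coeffs)
        lines.append(f"{n}  [{cstr:<44}]  {m.r2:.4f}  {m.adj_r2:.4f}  {m.rmse:.4f}")
    return "\n".join(lines)
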