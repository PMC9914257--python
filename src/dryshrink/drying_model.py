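"""Moisture bookkeeping and the polynomial moisture-ratio model.

Dry-basis moisture content is ``MC(t) = (m(t) - m_d) / m_d`` and the
moisture ratio ``MR(t) = MC(t) / MC(0)`` starts at exactly 1.  The model
links MR to the projected-area shrinkage S through an n-th order
polynomial ``MR = a0 + a1 S + ... + an S^n``, i.e. a model linear in its
parameters with regressor (information) vector ``phi = [1, S, ..., S^n]``.

The default sampling period is 0.5 min (one frame and mass reading every
30 s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "DEFAULT_SAMPLE_PERIOD_MIN",
    "ParameterVector",
    "MoistureSeries",
    "moisture_content",
    "moisture_ratio",
    "phi",
    "predict_mr",
    "save_model",
    "load_model",
]

DEFAULT_SAMPLE_PERIOD_MIN = 0.5


@dataclass(frozen=True)
class ParameterVector:
    """Coefficients [a0, ..., an] of the MR(S) polynomial; Q = n + 1."""

    coefficients: np.ndarray

    def __post_init__(self):
        coeffs = np.atleast_1d(np.asarray(self.coefficients, dtype=np.float64))
        if coeffs.ndim != 1 or coeffs.size < 2:
            raise DataError("parameter vector needs at least 2 coefficients (order >= 1)")
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def order(self) -> int:
        return self.coefficients.size - 1

    @property
    def q(self) -> int:
        return self.coefficients.size


@dataclass(frozen=True)
class MoistureSeries:
    """Time-indexed mass, moisture content and moisture ratio."""

    times: np.ndarray  # minutes
    mc: np.ndarray  # g water / g dry matter
    mr: np.ndarray  # dimensionless, 1 at the first sample

    @classmethod
    def from_mass(
        cls, times: Sequence[float], mass: Sequence[float], dry_mass: float
    ) -> "MoistureSeries":
        times = np.asarray(times, dtype=np.float64)
        mass = np.asarray(mass, dtype=np.float64)
        if times.shape != mass.shape:
            raise DataError("times and mass differ in length")
        mc = np.array([moisture_content(m, dry_mass) for m in mass])
        return cls(times=times, mc=mc, mr=moisture_ratio(mc))


def moisture_content(m: float, m_d: float) -> float:
    """Dry-basis moisture content (m - m_d) / m_d in g/g."""
    if m_d <= 0:
        raise DataError(f"dry mass must be positive, got {m_d}")
    if m < m_d:
        raise DataError(f"mass {m} below dry mass {m_d}: negative moisture")
    return (m - m_d) / m_d


def moisture_ratio(mc_series: Sequence[float]) -> np.ndarray:
    """Normalise a moisture-content series by its initial value.

    The first element of the result is exactly 1.
    """
    mc = np.asarray(mc_series, dtype=np.float64)
    if mc.size == 0:
        raise DataError("empty moisture-content series")
    if mc[0] <= 0:
        raise DataError("initial moisture content must be positive")
    mr = mc / mc[0]
    mr[0] = 1.0
    return mr


def phi(s: float | np.ndarray, n: int) -> np.ndarray:
    """Information vector [1, S, S^2, ..., S^n].

    For an array of shrinkage values the result has one row per value
    (a Vandermonde design matrix).
    """
    if n < 1:
        raise DataError(f"polynomial order must be >= 1, got {n}")
    s = np.asarray(s, dtype=np.float64)
    return np.vander(np.atleast_1d(s), n + 1, increasing=True) if s.ndim else np.power(
        s, np.arange(n + 1)
    )


def predict_mr(
    alpha: ParameterVector | Sequence[float], s: float | np.ndarray
) -> float | np.ndarray:
    """Evaluate the polynomial model at shrinkage ``s`` by Horner's scheme."""
    coeffs = alpha.coefficients if isinstance(alpha, ParameterVector) else np.asarray(
        alpha, dtype=np.float64
    )
    s = np.asarray(s, dtype=np.float64)
    out = np.full_like(s, coeffs[-1], dtype=np.float64)
    for c in coeffs[-2::-1]:
        out = out * s + c
    return float(out) if out.ndim == 0 else out


def save_model(
    path: str | Path,
    alpha: ParameterVector | Sequence[float],
    *,
    metrics: dict | None = None,
    provenance: dict | None = None,
) -> None:
    """Write a fitted model as JSON (order, coefficients, metrics, provenance)."""
    pv = alpha if isinstance(alpha, ParameterVector) else ParameterVector(np.asarray(alpha))
    payload = {
        "order": pv.order,
        "coefficients": [float(c) for c in pv.coefficients],
        "metrics": metrics or {},
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> tuple[ParameterVector, dict]:
    """Read a model JSON; returns (parameters, full payload)."""
    payload = json.loads(Path(path).read_text())
    try:
        coeffs = np.asarray(payload["coefficients"], dtype=np.float64)
        order = int(payload["order"])
    except (KeyError, TypeError, ValueError) as exc:
        raise DataError(f"malformed model file {path}: {exc}") from exc
    if coeffs.size != order + 1:
        raise DataError(
            f"model file {path}: order {order} inconsistent with "
            f"{coeffs.size} coefficients"
        )
    return ParameterVector(coeffs), payload


def read_series_csv(path: str | Path) -> pd.DataFrame:
    """Read a series CSV holding some of time_min, mass_g, shrinkage, moisture_ratio."""
    df = pd.read_csv(path)
    if "shrinkage" not in df.columns:
        raise DataError(f"series file {path} lacks a 'shrinkage' column")
    return df
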