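"""Clonogenic survival and population growth kinetics.

Implements the linear-quadratic (LQ) model of reproductive cell survival
after a single acute radiation dose,

    S(D) = exp(-alpha * D - beta * D**2),

with ``alpha`` (1/Gy) the single-track and ``beta`` (1/Gy^2) the two-track
lethality coefficient, together with exponential growth-rate fitting for
cell-count / tumor-volume trajectories and cumulative population-doubling
accounting for serially passaged cultures.

Surviving fractions are normalized to the 0 Gy plating efficiency, so
S(0) = 1 by construction — the standard clonogenic-assay convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LQParameters",
    "ClonogenicRecord",
    "GrowthFit",
    "InsufficientDataError",
    "lq_surviving_fraction",
    "lq_from_survival_points",
    "fit_lq",
    "fit_exponential_growth",
    "cumulative_population_doublings",
]


class InsufficientDataError(ValueError):
    """Raised when a fit has fewer qualifying points than it needs.

    Attributes
    ----------
    n_points : int
        Number of qualifying points that were available.
    """

    def __init__(self, message: str, n_points: int):
        super().__init__(message)
        self.n_points = n_points


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic survival parameters (alpha: 1/Gy, beta: 1/Gy^2)."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha >= 0 and self.beta >= 0):
            raise ValueError(
                f"alpha and beta must be non-negative, got ({self.alpha}, {self.beta})"
            )


@dataclass(frozen=True)
class ClonogenicRecord:
    """One dish of a clonogenic assay: dose (Gy), cells plated, colonies counted."""

    dose: float
    cells_plated: int
    colonies: int

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError(f"dose must be non-negative, got {self.dose}")
        if not (0 <= self.colonies <= self.cells_plated):
            raise ValueError(
                f"need 0 <= colonies <= cells_plated, got {self.colonies}/{self.cells_plated}"
            )


@dataclass(frozen=True)
class GrowthFit:
    """Exponential fit ln(value) ~ log_intercept + rate * t.

    ``doubling_time`` is ln2/rate for positive rates and NaN otherwise.
    """

    rate: float
    log_intercept: float
    r_squared: float
    doubling_time: float
    n_points: int


def lq_surviving_fraction(params: LQParameters, dose) -> float | np.ndarray:
    """Surviving fraction S(D) = exp(-alpha*D - beta*D^2).

    ``dose`` may be a scalar or array of non-negative doses in Gy.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    s = np.exp(-params.alpha * d - params.beta * d * d)
    return float(s) if np.isscalar(dose) else s


def lq_from_survival_points(
    point1: tuple[float, float], point2: tuple[float, float]
) -> LQParameters:
    """Solve (alpha, beta) exactly through two (dose, surviving fraction) pairs.

    Solves the 2x2 linear system alpha*D + beta*D^2 = -ln S at the two
    distinct nonzero doses. Raises on singular systems (equal doses) and on
    non-positive survival.
    """
    (d1, s1), (d2, s2) = point1, point2
    if d1 <= 0 or d2 <= 0 or d1 == d2:
        raise ValueError("two distinct nonzero doses are required")
    if s1 <= 0 or s2 <= 0 or s1 > 1 or s2 > 1:
        raise ValueError("surviving fractions must lie in (0, 1]")
    a = np.array([[d1, d1 * d1], [d2, d2 * d2]], dtype=float)
    y = -np.log([s1, s2])
    alpha, beta = np.linalg.solve(a, y)
    return LQParameters(alpha=float(alpha), beta=float(beta))


def _survival_table(records: Sequence[ClonogenicRecord]) -> pd.DataFrame:
    """Per-dose surviving fraction normalized by the 0 Gy plating efficiency."""
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        {
            "dose": [r.dose for r in records],
            "cells": [r.cells_plated for r in records],
            "colonies": [r.colonies for r in records],
        }
    )
    zero = df[df["dose"] == 0]
    if zero.empty:
        raise ValueError("0 Gy records are required to estimate plating efficiency")
    pe = zero["colonies"].sum() / zero["cells"].sum()
    if pe <= 0:
        raise ValueError("plating efficiency is zero; cannot normalize survival")
    per_dose = df.groupby("dose", as_index=False).sum(numeric_only=True)
    per_dose["survival"] = per_dose["colonies"] / (per_dose["cells"] * pe)
    return per_dose


def fit_lq(
    records: Sequence[ClonogenicRecord], method: str = "least_squares"
) -> LQParameters:
    """Fit the LQ model to clonogenic records.

    method="interpolate"
        Exact solve through exactly two distinct nonzero doses.
    method="least_squares"
        Weighted non-negative least squares on -ln S over >=3 distinct
        doses, with per-dose weights equal to total colony counts
        (Poisson-motivated); alpha, beta >= 0 enforced. Doses where no
        colony grew carry zero weight and are excluded from the log fit
        (they would error under interpolate).
    """
    tab = _survival_table(records)
    nz = tab[tab["dose"] > 0]
    if method == "least_squares":
        nz = nz[nz["survival"] > 0]
    elif np.any(nz["survival"] <= 0):
        bad = nz.loc[nz["survival"] <= 0, "dose"].tolist()
        raise ValueError(f"surviving fraction is zero at doses {bad}; cannot take log")
    doses = nz["dose"].to_numpy(float)
    neglog_s = -np.log(nz["survival"].to_numpy(float))

    if method == "interpolate":
        if len(doses) != 2:
            raise ValueError(
                f"interpolate requires exactly two distinct nonzero doses, got {len(doses)}"
            )
        return lq_from_survival_points(
            (doses[0], float(np.exp(-neglog_s[0]))), (doses[1], float(np.exp(-neglog_s[1])))
        )
    if method == "least_squares":
        if len(doses) < 3:
            raise ValueError(
                f"least_squares requires >=3 distinct nonzero doses, got {len(doses)}"
            )
        w = np.sqrt(nz["colonies"].to_numpy(float))
        design = np.column_stack([doses, doses**2])
        coef, _ = optimize.nnls(design * w[:, None], neglog_s * w)
        return LQParameters(alpha=float(coef[0]), beta=float(coef[1]))
    raise ValueError(f"unknown method {method!r}")


def fit_exponential_growth(
    times: Iterable[float],
    values: Iterable[float],
    min_value: float = 0.0,
) -> GrowthFit:
    """OLS fit of ln(value) on time, restricted to values >= ``min_value``.

    ``min_value`` implements a detection / size threshold (e.g. fitting in
    vivo growth only above 200 mm^3 tumor volume, or an in silico detection
    size in cells), so lag phases below the threshold do not bias the rate.
    Duplicate time points are averaged in log space before fitting. Requires
    at least three qualifying points.
    """
    t = np.asarray(list(times), dtype=float)
    v = np.asarray(list(values), dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values must have equal length")
    if np.any(v <= 0):
        raise ValueError("values must be positive for a log-linear fit")
    keep = v >= min_value
    t, v = t[keep], v[keep]
    # average duplicate times in log space
    if t.size:
        df = pd.DataFrame({"t": t, "logv": np.log(v)}).groupby("t", as_index=False).mean()
        t = df["t"].to_numpy()
        logv = df["logv"].to_numpy()
    else:
        logv = np.array([])
    if t.size < 3:
        raise InsufficientDataError(
            f"need >=3 points at or above min_value={min_value}, got {t.size}", int(t.size)
        )
    res = stats.linregress(t, logv)
    rate = float(res.slope)
    return GrowthFit(
        rate=rate,
        log_intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        doubling_time=float(np.log(2) / rate) if rate > 0 else float("nan"),
        n_points=int(t.size),
    )


def cumulative_population_doublings(
    passages: Sequence[tuple[float, float, float]]
) -> pd.DataFrame:
    """Cumulative population doublings over serial passages.

    ``passages`` is a sequence of (plated, harvested, day) with strictly
    increasing days and positive counts. Each passage contributes
    log2(harvested / plated) doublings; the per-interval doubling rate
    divides by the interval length (first interval measured from day 0).

    Returns a DataFrame with columns day, doublings, cumulative_doublings,
    interval_days, doubling_rate (doublings/day).
    """
    if not passages:
        raise ValueError("no passages")
    plated = np.array([p[0] for p in passages], dtype=float)
    harvested = np.array([p[1] for p in passages], dtype=float)
    days = np.array([p[2] for p in passages], dtype=float)
    if np.any(plated <= 0) or np.any(harvested <= 0):
        raise ValueError("counts must be positive")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    doublings = np.log2(harvested / plated)
    intervals = np.diff(np.concatenate([[0.0], days]))
    return pd.DataFrame(
        {
            "day": days,
            "doublings": doublings,
            "cumulative_doublings": np.cumsum(doublings),
            "interval_days": intervals,
            "doubling_rate": doublings / intervals,
        }
    )
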