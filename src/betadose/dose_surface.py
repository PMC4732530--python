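"""Reduction of the forward dose model to a linear dose surface.

Because the cumulative dose is a fixed linear combination of the two
deposition-ratio parameters, the forward model collapses exactly onto

    D(r_i, r_t) = a * r_i + slope_b * r_t + intercept_b

in mSv per 1000 kBq/m2 of Cs-137 deposition over one year.  This module
performs the two-stage least-squares reduction (dose vs r_i at fixed
r_t, then intercept vs r_t), evaluates the surface, and scales unit
doses by a location's Cs-137 deposition density.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nuclides import NuclideSet, RatioSet, cumulative_dose

__all__ = [
    "Parameterization",
    "FitTable",
    "DoseResult",
    "PUBLISHED_FIT",
    "DEFAULT_RI_GRID",
    "DEFAULT_RT_LIST",
    "scan_fit",
    "fit_b_line",
    "evaluate",
    "apply_deposition",
]


class SingularFitError(ValueError):
    """Raised when a least-squares design is degenerate."""


@dataclass(frozen=True)
class Parameterization:
    """Coefficients of the linear one-year dose surface.

    ``a``: mSv per unit r_i; ``slope_b``: mSv per unit r_t;
    ``intercept_b``: mSv — all per 1000 kBq/m2 of Cs-137 deposition.
    """

    a: float
    slope_b: float
    intercept_b: float

    def __post_init__(self) -> None:
        for v in (self.a, self.slope_b, self.intercept_b):
            if not np.isfinite(v):
                raise ValueError("parameterization coefficients must be finite")


#: The published one-year dose-surface constants (mSv per 1000 kBq/m2).
PUBLISHED_FIT = Parameterization(a=1.1165, slope_b=31.032, intercept_b=50.009)

#: Default r_i scan grid and r_t list, mirroring the published dose-rate curves.
DEFAULT_RI_GRID = (5.0, 9.2, 20.0, 40.0, 100.0, 200.0)
DEFAULT_RT_LIST = (0.1, 0.5, 1.0, 5.0, 10.0, 50.0)


@dataclass(frozen=True)
class FitTable:
    """Per-r_t linear fits of cumulative dose against r_i.

    Columns: ``r_t`` (unique, positive), ``a_rt`` (slope in r_i at that
    r_t) and ``b`` (intercept at that r_t), mSv per 1000 kBq/m2.
    """

    r_t: np.ndarray
    a_rt: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        r_t = np.asarray(self.r_t, dtype=float)
        a_rt = np.asarray(self.a_rt, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if not (r_t.shape == a_rt.shape == b.shape) or r_t.ndim != 1:
            raise ValueError("FitTable columns must be matching 1-d arrays")
        if len(np.unique(r_t)) != len(r_t) or np.any(r_t <= 0):
            raise ValueError("r_t values must be unique and positive")
        object.__setattr__(self, "r_t", r_t)
        object.__setattr__(self, "a_rt", a_rt)
        object.__setattr__(self, "b", b)

    def __len__(self) -> int:
        return len(self.r_t)


@dataclass(frozen=True)
class DoseResult:
    """Unit dose (mSv per 1000 kBq/m2) and absolute dose (mSv) at a location."""

    d_unit: float
    d_a: float


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least-squares slope/intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise SingularFitError("need at least two distinct abscissa values")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def scan_fit(model: NuclideSet, r_i_grid=DEFAULT_RI_GRID, r_t_list=DEFAULT_RT_LIST) -> FitTable:
    """Fit cumulative dose against r_i for each r_t by ordinary least squares.

    The forward model is exactly linear in the ratios, so the fitted
    slope is the same for every r_t (up to rounding) and the residuals
    vanish; the fit mirrors how the published constants were obtained.
    """
    r_i_grid = np.asarray(r_i_grid, dtype=float)
    if r_i_grid.size < 2 or np.ptp(r_i_grid) == 0:
        raise SingularFitError("r_i grid must contain at least two distinct values")
    slopes, intercepts = [], []
    for r_t in r_t_list:
        doses = [cumulative_dose(model, RatioSet(r_i, r_t)) for r_i in r_i_grid]
        slope, intercept = _ols_line(r_i_grid, np.array(doses))
        slopes.append(slope)
        intercepts.append(intercept)
    return FitTable(np.asarray(r_t_list, dtype=float), np.array(slopes), np.array(intercepts))


def fit_b_line(table: FitTable) -> tuple[float, float]:
    """Re-fit the per-r_t intercepts b against r_t: returns (slope_b, intercept_b)."""
    if len(table) < 2:
        raise SingularFitError("need at least two rows to fit b(r_t)")
    return _ols_line(table.r_t, table.b)


def evaluate(param: Parameterization, ratios: RatioSet) -> float:
    """Unit dose D(r_i, r_t) = a*r_i + slope_b*r_t + intercept_b (mSv/1000 kBq/m2)."""
    return param.a * ratios.r_i + param.slope_b * ratios.r_t + param.intercept_b


def apply_deposition(d_unit: float, a_cs137: float) -> float:
    """Scale a unit dose by the Cs-137 deposition density (kBq/m2) -> mSv."""
    if a_cs137 < 0:
        raise ValueError(f"deposition density must be >= 0, got {a_cs137}")
    return d_unit * a_cs137 / 1000.0
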