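"""Multilevel B-spline approximation (MBA) of scattered geographic data.

Implements the classic two-stage scheme for scattered-data fitting with
uniform cubic tensor-product B-splines: the BA step computes, for every
data point, the least-deviation control coefficients over its 4x4
neighbourhood and blends overlapping candidates with weights w^2; the
multilevel step applies BA coarse-to-fine on the residuals of the
previous level, halving the lattice spacing each time, so the hierarchy
sum approximates the data increasingly closely while staying smooth.

This is the stage used to spread sparse Te-129m/Cs-137 ratio
measurements (and the final per-location doses) onto regular lon/lat
rasters.  Coefficients that no data point touches stay at zero, so the
surface decays toward zero far outside the data hull; such queries are
flagged, not masked.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Normalization",
    "ScatterSet",
    "ControlLattice",
    "ControlLatticeHierarchy",
    "GridSpec",
    "GridField",
    "normalize_coords",
    "ba_fit",
    "mbs_fit",
    "evaluate_lattice",
    "evaluate_field",
    "interpolate_missing_ratios",
    "read_esri_ascii",
    "write_esri_ascii",
]

logger = logging.getLogger(__name__)

NODATA = -9999.0


class CannotInterpolateError(ValueError):
    """No measured values are available to fit from."""


class ResolutionLimitError(ValueError):
    """The requested hierarchy would need lattice cells finer than 1e-6."""


# ---------------------------------------------------------------------------
# coordinate normalization

@dataclass(frozen=True)
class Normalization:
    """Affine lon/lat -> unit-square map with local-planar metric metadata.

    Longitudes are scaled by cos(mean latitude) before normalization so
    the recorded ``aspect`` (metric width / metric height) describes the
    true ground-distance anisotropy of the box; the per-axis unit-square
    map itself sends the box corners to (0,0) and (1,1).
    """

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    cos_lat: float

    def __post_init__(self) -> None:
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ValueError("bounding box must have positive extent on both axes")

    @property
    def aspect(self) -> float:
        return (self.lon_max - self.lon_min) * self.cos_lat / (self.lat_max - self.lat_min)

    def to_unit(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        u = (lon - self.lon_min) * self.cos_lat
        x = u / ((self.lon_max - self.lon_min) * self.cos_lat)
        y = (lat - self.lat_min) / (self.lat_max - self.lat_min)
        return x, y

    def from_unit(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = self.lon_min + x * (self.lon_max - self.lon_min)
        lat = self.lat_min + y * (self.lat_max - self.lat_min)
        return lon, lat


def normalize_coords(lons, lats, bbox) -> tuple[np.ndarray, np.ndarray, Normalization]:
    """Map lon/lat points into the unit square over ``bbox``.

    ``bbox`` is (lon_min, lat_min, lon_max, lat_max).  Returns unit-square
    x, y and the invertible :class:`Normalization` record.
    """
    lon_min, lat_min, lon_max, lat_max = bbox
    mean_lat = 0.5 * (lat_min + lat_max)
    norm = Normalization(lon_min, lat_min, lon_max, lat_max, float(np.cos(np.radians(mean_lat))))
    x, y = norm.to_unit(lons, lats)
    return x, y, norm


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class ScatterSet:
    """Scattered values at unit-square coordinates, with provenance."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    normalization: Normalization | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if not (x.shape == y.shape == v.shape) or x.ndim != 1 or x.size < 1:
            raise ValueError("x, y, values must be matching non-empty 1-d arrays")
        if np.any((x < 0) | (x > 1) | (y < 0) | (y > 1)):
            raise ValueError("scatter points must lie in the unit square")
        if not np.all(np.isfinite(v)):
            raise ValueError("scatter values must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ControlLattice:
    """One uniform cubic B-spline control lattice over the unit square.

    ``coeffs`` has shape (mx+3, my+3) for an mx-by-my cell lattice: the
    one-cell margin on each side is the support cubic B-splines need.
    """

    coeffs: np.ndarray
    mx: int
    my: int

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (self.mx + 3, self.my + 3):
            raise ValueError("coeffs shape must be (mx+3, my+3)")
        object.__setattr__(self, "coeffs", c)


@dataclass(frozen=True)
class ControlLatticeHierarchy:
    """Coarse-to-fine list of control lattices; evaluation sums all levels."""

    levels: tuple[ControlLattice, ...]
    normalization: Normalization | None = None

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValueError("hierarchy needs at least one level")


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat raster geometry: SW corner, cell size, cell counts."""

    west: float
    south: float
    cellsize: float
    ncols: int
    nrows: int

    def __post_init__(self) -> None:
        if self.cellsize <= 0 or self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid spec needs positive cell size and counts")

    @property
    def north(self) -> float:
        return self.south + self.nrows * self.cellsize

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cellsize

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-d arrays of cell centres, row 0 at the north edge."""
        lons = self.west + (np.arange(self.ncols) + 0.5) * self.cellsize
        lats = self.north - (np.arange(self.nrows) + 0.5) * self.cellsize
        return np.meshgrid(lons, lats)


@dataclass(frozen=True)
class GridField:
    """A raster of values on a :class:`GridSpec`, row-major from the NW corner."""

    spec: GridSpec
    values: np.ndarray
    nodata: float = NODATA
    extrapolated: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError("values shape must be (nrows, ncols)")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# cubic uniform B-spline machinery

def _bspline_weights(t: np.ndarray) -> np.ndarray:
    """The four cubic uniform B-spline basis values at local coordinate t."""
    t = np.asarray(t, dtype=float)
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1.0 - t) ** 3 / 6.0,
            (3.0 * t3 - 6.0 * t2 + 4.0) / 6.0,
            (-3.0 * t3 + 3.0 * t2 + 3.0 * t + 1.0) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )


def _locate(coord: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Cell index (clamped to [0, m-1]) and local coordinate for each point."""
    p = np.asarray(coord, dtype=float) * m
    i = np.clip(np.floor(p).astype(int), 0, m - 1)
    return i, p - i


def _point_weights(x, y, mx, my):
    ix, sx = _locate(x, mx)
    iy, sy = _locate(y, my)
    wx = _bspline_weights(sx)  # (N, 4)
    wy = _bspline_weights(sy)
    w = wx[:, :, None] * wy[:, None, :]  # (N, 4, 4)
    return ix, iy, w


def ba_fit(scatter: ScatterSet, resolution: int | tuple[int, int]) -> ControlLattice:
    """Single-level B-spline approximation of scattered data.

    For each data point the candidate coefficients over its 4x4 control
    neighbourhood are ``w * z / sum(w^2)``; where neighbourhoods overlap
    the candidates are blended with weights ``w^2``.  Coefficients with
    no contributing point default to 0.  A single isolated point is
    reproduced exactly (algebraic identity of the two formulas).
    """
    mx, my = (resolution, resolution) if np.isscalar(resolution) else resolution
    if mx < 1 or my < 1:
        raise ValueError("lattice resolution must be at least one cell")
    ix, iy, w = _point_weights(scatter.x, scatter.y, mx, my)
    sum_w2 = np.einsum("nkl,nkl->n", w, w)
    phi_c = w * (scatter.values / sum_w2)[:, None, None]  # per-point candidates
    num = np.zeros((mx + 3, my + 3))
    den = np.zeros((mx + 3, my + 3))
    offs = np.arange(4)
    rows = (ix[:, None] + offs)[:, :, None]  # (N, 4, 1)
    cols = (iy[:, None] + offs)[:, None, :]  # (N, 1, 4)
    rows = np.broadcast_to(rows, w.shape)
    cols = np.broadcast_to(cols, w.shape)
    np.add.at(num, (rows.ravel(), cols.ravel()), (w * w * phi_c).ravel())
    np.add.at(den, (rows.ravel(), cols.ravel()), (w * w).ravel())
    coeffs = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return ControlLattice(coeffs, mx, my)


def evaluate_lattice(lattice: ControlLattice, x, y) -> np.ndarray:
    """Tensor cubic B-spline evaluation of one lattice at unit-square points."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    ix, iy, w = _point_weights(x, y, lattice.mx, lattice.my)
    offs = np.arange(4)
    block = lattice.coeffs[(ix[:, None] + offs)[:, :, None], (iy[:, None] + offs)[:, None, :]]
    return np.einsum("nkl,nkl->n", w, block)


def mbs_fit(
    scatter: ScatterSet,
    n_levels: int = 6,
    base_resolution: int | tuple[int, int] = 4,
) -> ControlLatticeHierarchy:
    """Multilevel B-spline fit: BA on residuals, spacing halved per level."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    mx, my = (
        (base_resolution, base_resolution) if np.isscalar(base_resolution) else base_resolution
    )
    finest = max(mx, my) * 2 ** (n_levels - 1)
    if 1.0 / finest < 1e-6:
        raise ResolutionLimitError(
            f"finest lattice cell 1/{finest} is below the 1e-6 resolution limit"
        )
    residual = scatter.values.copy()
    levels = []
    for _ in range(n_levels):
        level_scatter = ScatterSet(scatter.x, scatter.y, residual, scatter.normalization)
        lattice = ba_fit(level_scatter, (mx, my))
        residual = residual - evaluate_lattice(lattice, scatter.x, scatter.y)
        levels.append(lattice)
        mx, my = 2 * mx, 2 * my
    return ControlLatticeHierarchy(tuple(levels), scatter.normalization)


def _evaluate_points(hierarchy: ControlLatticeHierarchy, x, y):
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    outside = (x < 0) | (x > 1) | (y < 0) | (y > 1)
    xc = np.clip(x, 0.0, 1.0)
    yc = np.clip(y, 0.0, 1.0)
    total = np.zeros(x.shape)
    for lattice in hierarchy.levels:
        total += evaluate_lattice(lattice, xc, yc)
    return total, outside


def evaluate_field(hierarchy: ControlLatticeHierarchy, where) -> GridField | np.ndarray:
    """Evaluate the hierarchy on a :class:`GridSpec` or at (x, y) point arrays.

    Grid evaluation requires the hierarchy to carry its normalization
    (cell centres are lon/lat).  Point queries are unit-square
    coordinates; queries outside the unit square are evaluated at the
    clamped position and flagged.
    """
    if isinstance(where, GridSpec):
        if hierarchy.normalization is None:
            raise ValueError("grid evaluation needs a hierarchy with a normalization")
        lon, lat = where.cell_centers()
        x, y = hierarchy.normalization.to_unit(lon.ravel(), lat.ravel())
        vals, outside = _evaluate_points(hierarchy, x, y)
        return GridField(
            where,
            vals.reshape(where.nrows, where.ncols),
            extrapolated=outside.reshape(where.nrows, where.ncols),
        )
    x, y = where
    vals, outside = _evaluate_points(hierarchy, x, y)
    if np.any(outside):
        logger.info("evaluate_field: %d of %d queries outside the unit square (extrapolated)",
                    int(outside.sum()), outside.size)
    return vals


def interpolate_missing_ratios(
    lons,
    lats,
    values,
    grid_spec: GridSpec | None = None,
    bbox=None,
    n_levels: int = 6,
    base_resolution: int | tuple[int, int] = 4,
):
    """Fill missing values (NaN) by a multilevel B-spline fit of measured ones.

    Fits the hierarchy on the non-NaN entries, evaluates it at the NaN
    locations and (optionally) on ``grid_spec``.  Negative interpolated
    values are clamped to 0 (count logged); measured entries are never
    altered.

    Returns ``(filled, measured_mask, hierarchy, grid_field)`` where
    ``grid_field`` is None when no grid was requested.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    values = np.asarray(values, dtype=float)
    measured = np.isfinite(values)
    if not measured.any():
        raise CannotInterpolateError("no measured values to interpolate from")
    if bbox is None:
        if grid_spec is not None:
            bbox = (grid_spec.west, grid_spec.south, grid_spec.east, grid_spec.north)
        else:
            pad_x = max(np.ptp(lons), 1e-6) * 0.05
            pad_y = max(np.ptp(lats), 1e-6) * 0.05
            bbox = (lons.min() - pad_x, lats.min() - pad_y,
                    lons.max() + pad_x, lats.max() + pad_y)
    x, y, norm = normalize_coords(lons, lats, bbox)
    scatter = ScatterSet(np.clip(x[measured], 0, 1), np.clip(y[measured], 0, 1),
                         values[measured], norm)
    hierarchy = mbs_fit(scatter, n_levels=n_levels, base_resolution=base_resolution)

    filled = values.copy()
    if (~measured).any():
        est, _ = _evaluate_points(hierarchy, x[~measured], y[~measured])
        n_neg = int((est < 0).sum())
        if n_neg:
            logger.info("interpolate_missing_ratios: clamped %d negative estimates to 0", n_neg)
        filled[~measured] = np.clip(est, 0.0, None)

    grid_field = None
    if grid_spec is not None:
        grid_field = evaluate_field(hierarchy, grid_spec)
    return filled, measured, hierarchy, grid_field


# ---------------------------------------------------------------------------
# plain-text raster I/O (ESRI ASCII grid dialect)

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value")


def write_esri_ascii(field: GridField, path) -> None:
    """Write a raster as an ESRI ASCII grid.

    Header lines are ``<key> <value>`` separated by a single space, keys
    in the order ncols, nrows, xllcorner, yllcorner, cellsize,
    NODATA_value; data rows run north to south, values separated by
    single spaces, formatted with ``repr``-shortest float formatting.
    """
    spec = field.spec
    vals = np.where(np.isfinite(field.values), field.values, field.nodata)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {spec.ncols}\n")
        fh.write(f"nrows {spec.nrows}\n")
        fh.write(f"xllcorner {spec.west:g}\n")
        fh.write(f"yllcorner {spec.south:g}\n")
        fh.write(f"cellsize {spec.cellsize:g}\n")
        fh.write(f"NODATA_value {field.nodata:g}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_esri_ascii(path) -> GridField:
    """Read an ESRI ASCII grid written by :func:`write_esri_ascii`."""
    header = {}
    data_lines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] in _HEADER_KEYS and len(header) < len(_HEADER_KEYS):
                header[parts[0]] = float(parts[1])
            else:
                data_lines.append([float(v) for v in parts])
    spec = GridSpec(
        west=header["xllcorner"],
        south=header["yllcorner"],
        cellsize=header["cellsize"],
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
    )
    values = np.array(data_lines)
    nodata = header.get("NODATA_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return GridField(spec, values, nodata=nodata)
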