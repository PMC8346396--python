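"""Regular geographic grids and the masked raster layers built on them.

All grids in this package are geographic (WGS84-style decimal degrees) and
cell-center referenced: row 0 is the northernmost row, column 0 the
westernmost column, and ``lat(i) = north - i * dlat``,
``lon(j) = west + j * dlon`` give the center of cell ``(i, j)``.  Distances
between points are Euclidean in degree space throughout — the interpolation
circles are specified by an angular radius, so degree space keeps a single
distance metric for circle membership and inverse-distance weights alike.
The latitude-dependent anisotropy this implies is accepted and documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridGeometry",
    "Grid",
    "DemGrid",
    "CoefficientGrid",
    "mask_elevation",
    "anomaly_map",
    "growing_season_length",
]


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular lat/lon grid, cell-center referenced.

    Parameters
    ----------
    north, west : float
        Latitude of the row-0 cell centers and longitude of the column-0
        cell centers, in decimal degrees.
    dlat, dlon : float
        Positive cell spacings in degrees (latitude decreases with row
        index, longitude increases with column index).
    nrows, ncols : int
        Grid shape.
    """

    north: float
    west: float
    dlat: float
    dlon: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.dlat <= 0 or self.dlon <= 0:
            raise ValueError("cell spacings must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_lats(self) -> np.ndarray:
        return self.north - np.arange(self.nrows) * self.dlat

    def cell_lons(self) -> np.ndarray:
        return self.west + np.arange(self.ncols) * self.dlon

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return 2-D (lat, lon) center arrays of shape ``(nrows, ncols)``."""
        return np.meshgrid(self.cell_lats(), self.cell_lons(), indexing="ij")

    def bbox(self) -> tuple[float, float, float, float]:
        """(lat_min, lat_max, lon_min, lon_max) over cell centers."""
        lats, lons = self.cell_lats(), self.cell_lons()
        return float(lats.min()), float(lats.max()), float(lons.min()), float(lons.max())

    def nearest_cell(self, lat: float, lon: float) -> tuple[int, int]:
        """Index of the cell whose center is closest to ``(lat, lon)``."""
        i = int(np.clip(np.rint((self.north - lat) / self.dlat), 0, self.nrows - 1))
        j = int(np.clip(np.rint((lon - self.west) / self.dlon), 0, self.ncols - 1))
        return i, j


@dataclass
class Grid:
    """A single masked raster layer on a :class:`GridGeometry`.

    ``mask`` is True where the cell is valid.  Values at masked cells are
    kept as NaN and never enter statistics.
    """

    geometry: GridGeometry
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise ValueError("mask shape does not match geometry")
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def mean(self) -> float:
        if self.n_valid == 0:
            raise ValueError("grid has no valid cells")
        return float(np.nanmean(self.values[self.mask]))

    def std(self) -> float:
        return float(np.nanstd(self.values[self.mask]))

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        return Grid(self.geometry, np.array(values, dtype=float),
                    self.mask.copy() if mask is None else np.array(mask, dtype=bool))

    def allclose(self, other: "Grid", atol: float = 1e-9, rtol: float = 1e-9) -> bool:
        if self.geometry != other.geometry or not np.array_equal(self.mask, other.mask):
            return False
        a, b = self.values[self.mask], other.values[other.mask]
        return bool(np.allclose(a, b, atol=atol, rtol=rtol))


class DemGrid(Grid):
    """Digital elevation model: per-cell elevation in meters a.s.l."""


@dataclass
class CoefficientGrid:
    """Four interpolated regression-coefficient layers on one geometry.

    Layer order: intercept a0 (days), elevation coefficient a1 (days/m),
    longitude coefficient a2 (days/deg), latitude coefficient a3 (days/deg).
    """

    geometry: GridGeometry
    values: np.ndarray  # (4, nrows, ncols)
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4, *self.geometry.shape):
            raise ValueError("coefficient grid must have 4 layers matching the geometry")
        self.mask = np.asarray(self.mask, dtype=bool)

    def layer(self, k: int) -> Grid:
        return Grid(self.geometry, self.values[k].copy(), self.mask.copy())


def mask_elevation(grid: Grid, dem: DemGrid, max_elev: float = 1000.0) -> Grid:
    """Mask cells at or above ``max_elev`` meters a.s.l.

    The mapped product deliberately excludes high-elevation terrain where
    the observation network is too sparse to constrain the regression;
    cells with ``elevation >= max_elev`` are removed (strict threshold:
    exactly 1000 m is masked under the default).
    """
    if grid.geometry != dem.geometry:
        raise ValueError("grid and DEM geometries differ")
    keep = grid.mask & dem.mask & ~(dem.values >= max_elev)
    n_masked = int(grid.mask.sum() - keep.sum())
    if keep.sum() == 0:
        warnings.warn("elevation mask removed every cell", stacklevel=2)
    out = grid.copy_with(grid.values, keep)
    out.n_masked_by_elevation = n_masked  # type: ignore[attr-defined]
    return out


def anomaly_map(pheno: Grid) -> Grid:
    """Per-cell onset anomaly: cell value minus the spatial mean.

    Negative anomalies mark earlier-than-average onset, positive ones a
    delay.  The anomalies average to zero over the valid cells by
    construction.
    """
    if pheno.n_valid == 0:
        raise ValueError("cannot compute anomalies of a fully masked grid")
    return pheno.copy_with(pheno.values - pheno.mean())


def growing_season_length(first_spring: Grid, winter: Grid) -> float:
    """Mean growing-season length in days: winter onset minus first-spring onset.

    Cells where the winter phase precedes first spring contribute negative
    lengths; this is allowed but flagged with a warning since it normally
    indicates a degenerate interpolation.
    """
    if first_spring.geometry != winter.geometry or not np.array_equal(
        first_spring.mask, winter.mask
    ):
        raise ValueError("growing-season grids must share geometry and mask")
    diff = winter.values[winter.mask] - first_spring.values[first_spring.mask]
    if diff.size == 0:
        raise ValueError("no valid cells")
    if np.any(diff < 0):
        warnings.warn(
            f"{int((diff < 0).sum())} cells have winter onset before first spring",
            stacklevel=2,
        )
    return float(diff.mean())
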