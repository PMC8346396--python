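"""Circle-wise regression mapping of phenological onset dates.

The method follows Hopkins' bioclimatic law: onset dates vary linearly
with elevation, longitude and latitude, at least locally.  The domain is
covered by a lattice of large overlapping circles (default five rows by
six columns, radius 1.95 degrees); inside each circle an ordinary
least-squares fit of

    DOY = a0 + a1 h + a2 lon + a3 lat

is anchored at the circle center.  The four coefficients are then carried
to every grid cell by inverse-distance weighting (power 1) over the
circles containing that cell, and the linear model is evaluated with the
cell's own elevation and coordinates.  Cells at or above 1000 m a.s.l.
are masked: the observer network does not constrain high terrain.

:class:`PhenologyMapper` is the model object wrapping this chain;
``fit()`` returns a :class:`PhenologyMapResults` carrying the circle
fits, coefficient surfaces, the onset map and the validation surfaces.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import CoefficientGrid, DemGrid, Grid, anomaly_map, mask_elevation
from .observations import ObservationTable

logger = logging.getLogger(__name__)

__all__ = [
    "CircleSpec",
    "CircleFit",
    "build_circles",
    "assign_observations",
    "fit_circle",
    "idw_coefficients",
    "idw_scalar",
    "apply_model",
    "PhenologyMapper",
    "PhenologyMapResults",
]

DEFAULT_RADIUS = 1.95  # degrees
MIN_FIT_N = 8          # at least twice the number of regression parameters
COND_THRESHOLD = 1e10  # design matrices above this are treated as rank-deficient
_ZERO_DIST = 1e-9      # below this a cell sits on a circle center


@dataclass(frozen=True)
class CircleSpec:
    """One interpolation circle: center (degrees) and angular radius."""

    index: int
    center_lat: float
    center_lon: float
    radius: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("circle radius must be positive")


@dataclass
class CircleFit:
    """OLS result for one circle, anchored at its center.

    ``coeffs`` holds (a0, a1, a2, a3); ``ok`` is False when the circle had
    too few observations or a rank-deficient design, in which case it is
    excluded from interpolation rather than aborting the run.
    """

    index: int
    coeffs: np.ndarray | None
    n_obs: int
    ok: bool = True
    reason: str | None = None
    rmse_loocv: float | None = None

    @property
    def a0(self) -> float: return float(self.coeffs[0])
    @property
    def a1(self) -> float: return float(self.coeffs[1])
    @property
    def a2(self) -> float: return float(self.coeffs[2])
    @property
    def a3(self) -> float: return float(self.coeffs[3])


def build_circles(bbox: tuple[float, float, float, float], n_lat: int = 5,
                  n_lon: int = 6, radius: float = DEFAULT_RADIUS) -> list[CircleSpec]:
    """Lay out ``n_lat x n_lon`` circle centers evenly over a bounding box.

    The outermost centers lie on the bbox edges; with a single row or
    column the center sits midway.  ``bbox`` is (lat_min, lat_max,
    lon_min, lon_max) in degrees.
    """
    lat_min, lat_max, lon_min, lon_max = bbox
    if n_lat < 1 or n_lon < 1:
        raise ValueError("need at least one circle per axis")
    if (n_lat > 1 and lat_max <= lat_min) or (n_lon > 1 and lon_max <= lon_min):
        raise ValueError("degenerate bbox for a multi-circle layout")
    lats = np.linspace(lat_min, lat_max, n_lat) if n_lat > 1 \
        else np.array([(lat_min + lat_max) / 2])
    lons = np.linspace(lon_min, lon_max, n_lon) if n_lon > 1 \
        else np.array([(lon_min + lon_max) / 2])
    circles = []
    k = 0
    for la in lats:
        for lo in lons:
            circles.append(CircleSpec(k, float(la), float(lo), radius))
            k += 1
    return circles


def assign_observations(circles: list[CircleSpec],
                        table: ObservationTable) -> dict[int, np.ndarray]:
    """Row indices of the observations inside each circle.

    Membership is Euclidean distance in degree space, center-to-site,
    within the circle radius (inclusive); one observation can belong to
    several overlapping circles.  Rows outside every circle are counted as
    uncovered.
    """
    pts = table.coords  # (n, 2) lat, lon
    members: dict[int, np.ndarray] = {}
    covered = np.zeros(len(table), dtype=bool)
    for c in circles:
        d = np.hypot(pts[:, 0] - c.center_lat, pts[:, 1] - c.center_lon)
        idx = np.flatnonzero(d <= c.radius)
        members[c.index] = idx
        covered[idx] = True
    n_uncovered = int((~covered).sum())
    logger.info("assigned %d observations to %d circles (%d uncovered)",
                len(table), len(circles), n_uncovered)
    return members


def fit_circle(members: ObservationTable, index: int = 0,
               min_fit_n: int = MIN_FIT_N) -> CircleFit:
    """OLS fit of DOY on (1, elev, lon, lat) for one circle's observations.

    Circles with fewer than ``min_fit_n`` observations or an
    ill-conditioned design matrix return a failed-fit marker instead of
    raising, so a sparse circle never aborts a whole map.
    """
    n = len(members)
    if n < min_fit_n:
        return CircleFit(index, None, n, ok=False, reason="too-few-observations")
    X, y = members.design_matrix()
    if np.linalg.cond(X) > COND_THRESHOLD:
        return CircleFit(index, None, n, ok=False, reason="rank-deficient")
    res = sm.OLS(y, X).fit()
    return CircleFit(index, np.asarray(res.params, float), n)


def _idw_weights(circles: list[CircleSpec], fits: list[CircleFit],
                 geom) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell IDW weights over the fitted circles containing each cell.

    Returns (weights (n_ok, nr*nc), direct (n_ok, nr*nc) zero-distance
    indicator, ok_fit_indices).
    """
    ok = [f for f in fits if f.ok]
    if not ok:
        raise ValueError("no successfully fitted circles")
    by_index = {c.index: c for c in circles}
    lat2, lon2 = geom.cell_centers()
    cell_lat, cell_lon = lat2.ravel(), lon2.ravel()
    d = np.empty((len(ok), cell_lat.size))
    inside = np.empty_like(d, dtype=bool)
    for r, f in enumerate(ok):
        c = by_index[f.index]
        d[r] = np.hypot(cell_lat - c.center_lat, cell_lon - c.center_lon)
        inside[r] = d[r] <= c.radius
    direct = inside & (d < _ZERO_DIST)
    w = np.where(inside, 1.0 / np.maximum(d, _ZERO_DIST), 0.0)
    # zero-distance rule: a cell on a center copies that circle exactly
    has_direct = direct.any(axis=0)
    w[:, has_direct] = direct[:, has_direct].astype(float)
    return w, direct, np.array([f.index for f in ok])


def idw_coefficients(fits: list[CircleFit], circles: list[CircleSpec],
                     grid: DemGrid) -> CoefficientGrid:
    """Inverse-distance (power 1) interpolation of the coefficient fields.

    Every cell takes the 1/d-weighted mean of each coefficient over the
    fitted circles whose center lies within their radius of the cell; a
    cell coinciding with a center copies that circle's coefficients
    exactly.  Cells covered by no fitted circle are masked and counted.
    """
    geom = grid.geometry
    w, _, ok_idx = _idw_weights(circles, fits, geom)
    coeff_by_index = {f.index: f.coeffs for f in fits if f.ok}
    C = np.stack([coeff_by_index[i] for i in ok_idx])  # (n_ok, 4)
    wsum = w.sum(axis=0)
    covered = wsum > 0
    vals = np.full((4, geom.nrows * geom.ncols), np.nan)
    vals[:, covered] = (C.T @ w[:, covered]) / wsum[covered]
    n_uncovered = int((grid.mask.ravel() & ~covered).sum())
    if n_uncovered:
        warnings.warn(f"{n_uncovered} valid cells covered by no fitted circle",
                      stacklevel=2)
    mask = grid.mask & covered.reshape(geom.shape)
    return CoefficientGrid(geom, vals.reshape(4, *geom.shape), mask)


def idw_scalar(values_by_index: dict[int, float], fits: list[CircleFit],
               circles: list[CircleSpec], grid: Grid) -> Grid:
    """Same IDW routine applied to one scalar per circle (e.g. its RMSE)."""
    usable = [f for f in fits if f.ok and f.index in values_by_index
              and values_by_index[f.index] is not None]
    if not usable:
        raise ValueError("no circle carries a value to interpolate")
    geom = grid.geometry
    w, _, ok_idx = _idw_weights(circles, usable, geom)
    v = np.array([values_by_index[i] for i in ok_idx])
    wsum = w.sum(axis=0)
    covered = wsum > 0
    out = np.full(geom.nrows * geom.ncols, np.nan)
    out[covered] = (v @ w[:, covered]) / wsum[covered]
    mask = grid.mask & covered.reshape(geom.shape)
    return Grid(geom, out.reshape(geom.shape), mask)


def apply_model(coeffs: CoefficientGrid, dem: DemGrid) -> Grid:
    """Evaluate the interpolated linear model on the DEM.

    Cell onset = a0 + a1 h + a2 lon + a3 lat with the cell's own elevation
    and center coordinates; the output mask is the intersection of the
    coefficient and DEM masks.
    """
    if coeffs.geometry != dem.geometry:
        raise ValueError("coefficient grid and DEM geometries differ")
    lat2, lon2 = dem.geometry.cell_centers()
    a0, a1, a2, a3 = coeffs.values
    doy = a0 + a1 * dem.values + a2 * lon2 + a3 * lat2
    return Grid(dem.geometry, doy, coeffs.mask & dem.mask)


class PhenologyMapper:
    """Onset-date map interpolation model for one phenophase and year.

    Parameters
    ----------
    observations : ObservationTable
        The records entering the circle fits (already restricted to one
        phase and year by the caller or via ``select``).  Observations
        outside the mapped raster still inform the circles that contain
        them.
    dem : DemGrid
        Target elevation raster.
    bbox : tuple, optional
        (lat_min, lat_max, lon_min, lon_max) for the circle layout;
        defaults to the observation bounding box, mirroring a network-wide
        layout that extends beyond the mapped region.
    n_lat, n_lon, radius
        Circle lattice (defaults 5 x 6 circles of radius 1.95 degrees).
    min_fit_n : int
        Minimum observations per circle (default 8).
    max_elev : float
        Elevation mask threshold in meters (default 1000).
    """

    def __init__(self, observations: ObservationTable, dem: DemGrid, *,
                 circles: list[CircleSpec] | None = None,
                 bbox: tuple[float, float, float, float] | None = None,
                 n_lat: int = 5, n_lon: int = 6, radius: float = DEFAULT_RADIUS,
                 min_fit_n: int = MIN_FIT_N, max_elev: float = 1000.0):
        self.observations = observations
        self.dem = dem
        if circles is None:
            if bbox is None:
                df = observations.df
                bbox = (float(df.lat.min()), float(df.lat.max()),
                        float(df.lon.min()), float(df.lon.max()))
            circles = build_circles(bbox, n_lat=n_lat, n_lon=n_lon, radius=radius)
        self.circles = circles
        self.min_fit_n = min_fit_n
        self.max_elev = max_elev

    @classmethod
    def from_files(cls, observations_path, dem_path, *, phase_id=None,
                   year=None, schema=None, **kwargs) -> "PhenologyMapper":
        from .io import read_dem
        from .observations import read_observations
        table = read_observations(observations_path, schema)
        if phase_id is not None or year is not None:
            table = table.select(phase_id=phase_id, year=year)
        return cls(table, read_dem(dem_path), **kwargs)

    def fit(self) -> "PhenologyMapResults":
        members = assign_observations(self.circles, self.observations)
        fits = []
        for c in self.circles:
            idx = members[c.index]
            sub = self.observations.subset(idx) if len(idx) else None
            if sub is None or len(sub) < self.min_fit_n:
                fits.append(CircleFit(c.index, None, len(idx), ok=False,
                                      reason="too-few-observations"))
            else:
                fits.append(fit_circle(sub, c.index, self.min_fit_n))
        n_ok = sum(f.ok for f in fits)
        logger.info("fitted %d/%d circles", n_ok, len(fits))
        coeff_grid = idw_coefficients(fits, self.circles, self.dem)
        pheno = apply_model(coeff_grid, self.dem)
        pheno = mask_elevation(pheno, self.dem, self.max_elev)
        return PhenologyMapResults(self, fits, members, coeff_grid, pheno)


@dataclass
class PhenologyMapResults:
    """Fitted map: circle coefficients, their surfaces, and the onset grid."""

    model: PhenologyMapper
    circle_fits: list[CircleFit]
    membership: dict[int, np.ndarray]
    coefficient_grid: CoefficientGrid
    pheno_grid: Grid
    _loocv_surface: Grid | None = field(default=None, repr=False)

    def loocv(self) -> "PhenologyMapResults":
        """Compute per-circle leave-one-out RMSE and its IDW surface."""
        from .validation import loocv_circle
        for f in self.circle_fits:
            if not f.ok:
                continue
            sub = self.model.observations.subset(self.membership[f.index])
            try:
                f.rmse_loocv = loocv_circle(sub, min_fit_n=self.model.min_fit_n)
            except ValueError as exc:
                f.rmse_loocv = None
                logger.warning("circle %d LOOCV unavailable: %s", f.index, exc)
        rmse = {f.index: f.rmse_loocv for f in self.circle_fits if f.ok}
        self._loocv_surface = idw_scalar(rmse, self.circle_fits,
                                         self.model.circles, self.pheno_grid)
        return self

    @property
    def loocv_surface(self) -> Grid:
        if self._loocv_surface is None:
            self.loocv()
        return self._loocv_surface

    def circle_rmse_mean(self) -> float:
        """Unweighted mean RMSE_LOOCV over fittable circles."""
        vals = [f.rmse_loocv for f in self.circle_fits
                if f.ok and f.rmse_loocv is not None]
        if not vals:
            raise ValueError("no circle has a LOOCV value; call loocv() first")
        return float(np.mean(vals))

    def gridded_rmse_mean(self) -> float:
        """Grid-weighted mean of the interpolated RMSE_LOOCV surface."""
        return self.loocv_surface.mean()

    def anomaly(self) -> Grid:
        return anomaly_map(self.pheno_grid)

    def circle_table(self) -> pd.DataFrame:
        rows = []
        by_index = {c.index: c for c in self.model.circles}
        for f in self.circle_fits:
            c = by_index[f.index]
            rows.append({
                "circle": f.index, "center_lat": c.center_lat,
                "center_lon": c.center_lon, "n_obs": f.n_obs, "ok": f.ok,
                "a0": f.a0 if f.ok else np.nan, "a1": f.a1 if f.ok else np.nan,
                "a2": f.a2 if f.ok else np.nan, "a3": f.a3 if f.ok else np.nan,
                "rmse_loocv": f.rmse_loocv if f.rmse_loocv is not None else np.nan,
                "reason": f.reason,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n_ok = sum(f.ok for f in self.circle_fits)
        g = self.pheno_grid
        lines = [
            "Phenology map interpolation",
            "=" * 54,
            f"observations:        {len(self.model.observations)}",
            f"circles fitted:      {n_ok}/{len(self.circle_fits)}",
            f"grid cells mapped:   {g.n_valid}/{g.geometry.nrows * g.geometry.ncols}",
            f"gridded mean onset:  {g.mean():.1f} +/- {g.std():.1f} DOY",
        ]
        have_rmse = [f for f in self.circle_fits if f.rmse_loocv is not None]
        if have_rmse:
            lines.append(
                f"gridded RMSE_LOOCV:  {self.gridded_rmse_mean():.1f} "
                f"+/- {self.loocv_surface.std():.1f} days"
            )
        lines.append("")
        with pd.option_context("display.width", 120):
            lines.append(self.circle_table().to_string(index=False,
                                                       float_format="%.4g"))
        return "\n".join(lines)
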