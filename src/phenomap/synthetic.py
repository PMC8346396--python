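"""Synthetic observer networks, terrain, climate and NDVI with known truth.

The generator emulates the statistical structure the mapping method
assumes: onset dates lie on a locally linear surface in elevation,
longitude and latitude, perturbed by i.i.d. Gaussian observer noise and an
optional linear year trend,

    DOY(site, year) = a0* + a1* h + a2* lon + a3* lat
                      + beta (year - year0) + N(0, sigma^2).

Defaults are chosen for a Bavaria-sized domain and a first-spring-like
phase: sigma = 6 days (the magnitude of the best observed interpolation
uncertainty), beta = -0.25 days/yr (a typical late-20th-century spring
advance), elevation coefficient +3 days per 100 m, and mild west-east and
south-north gradients.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import TemperatureCube, doy_to_month
from .grids import DemGrid, Grid, GridGeometry
from .ndvi import COMPOSITE_DOYS, NdviSeries
from .observations import ObservationTable

__all__ = [
    "SyntheticWorld",
    "make_world",
    "sample_observations",
    "make_temperature",
    "make_coupled_onsets",
    "make_ndvi_series",
    "implied_spearman",
]

# Bavaria-like default domain (degrees)
DEFAULT_BBOX = (47.3, 50.5, 9.0, 13.9)  # lat_min, lat_max, lon_min, lon_max
DEFAULT_COEFFS = (-76.0, 0.03, 1.5, 3.0)  # a0 (days), a1 (d/m), a2 (d/deg E), a3 (d/deg N)


@dataclass
class SyntheticWorld:
    """A terrain plus the true coefficient fields generating onset dates."""

    dem: DemGrid
    coeff_fields: np.ndarray  # (4, nrows, ncols): a0*, a1*, a2*, a3* per cell
    sigma: float              # observer noise sd, days
    beta: float               # linear trend, days per year
    years: np.ndarray
    year0: int
    seed: int
    coeff_mode: str = "constant"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        self.years = np.asarray(self.years, dtype=int)

    @property
    def geometry(self) -> GridGeometry:
        return self.dem.geometry

    def true_field(self, year: int | None = None) -> Grid:
        """The noiseless onset-DOY surface for one year (days, unrounded)."""
        lat2, lon2 = self.geometry.cell_centers()
        a0, a1, a2, a3 = self.coeff_fields
        doy = a0 + a1 * self.dem.values + a2 * lon2 + a3 * lat2
        if year is not None:
            doy = doy + self.beta * (year - self.year0)
        return Grid(self.geometry, doy, self.dem.mask.copy())


def _smooth_surface(rng: np.random.Generator, geom: GridGeometry,
                    n_modes: int = 6) -> np.ndarray:
    """Smooth random field in [0, 1] from a low-order random cosine series."""
    lat2, lon2 = geom.cell_centers()
    lat_min, lat_max, lon_min, lon_max = geom.bbox()
    u = (lat2 - lat_min) / max(lat_max - lat_min, 1e-12)
    v = (lon2 - lon_min) / max(lon_max - lon_min, 1e-12)
    z = np.zeros(geom.shape)
    for _ in range(n_modes):
        fu, fv = rng.uniform(0.5, 2.5, 2)
        pu, pv = rng.uniform(0, 2 * np.pi, 2)
        amp = rng.uniform(0.3, 1.0)
        z += amp * np.cos(2 * np.pi * fu * u + pu) * np.cos(2 * np.pi * fv * v + pv)
    z -= z.min()
    return z / max(z.max(), 1e-12)


def make_world(
    *,
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX,
    shape: tuple[int, int] = (40, 40),
    coeffs: tuple[float, float, float, float] = DEFAULT_COEFFS,
    coeff_mode: str = "constant",
    coeff_amplitude: float = 0.3,
    sigma: float = 6.0,
    beta: float = -0.25,
    years: range | tuple[int, int] = (1951, 2019),
    elev_max: float = 1800.0,
    seed: int = 0,
) -> SyntheticWorld:
    """Generate a synthetic world: DEM plus true coefficient fields.

    The DEM is a smooth random surface clipped to [0, ``elev_max``] m.  In
    ``constant`` mode the four coefficients hold everywhere; in
    ``smooth-gradient`` mode each varies smoothly across the domain with
    relative amplitude ``coeff_amplitude`` around its base value, which is
    the regime the overlapping-circle regression is designed to track.
    """
    nr, nc = shape
    if nr < 1 or nc < 1:
        raise ValueError("grid shape must be positive")
    lat_min, lat_max, lon_min, lon_max = bbox
    if not (lat_max > lat_min and lon_max > lon_min):
        raise ValueError("degenerate bbox")
    geom = GridGeometry(
        north=lat_max, west=lon_min,
        dlat=(lat_max - lat_min) / max(nr - 1, 1),
        dlon=(lon_max - lon_min) / max(nc - 1, 1),
        nrows=nr, ncols=nc,
    )
    rng = np.random.default_rng(seed)
    elev = np.clip(_smooth_surface(rng, geom) * elev_max, 0.0, elev_max)
    dem = DemGrid(geom, elev, np.ones(geom.shape, bool))

    base = np.asarray(coeffs, float)
    fields = np.broadcast_to(base[:, None, None], (4, nr, nc)).copy()
    if coeff_mode == "smooth-gradient":
        for k in range(4):
            mod = _smooth_surface(rng, geom)  # in [0, 1]
            scale = coeff_amplitude * (abs(base[k]) if base[k] != 0 else 1.0)
            fields[k] = base[k] + scale * (2 * mod - 1)
    elif coeff_mode != "constant":
        raise ValueError(f"unknown coeff_mode {coeff_mode!r}")

    if isinstance(years, tuple):
        years = range(years[0], years[1] + 1)
    yr = np.asarray(list(years), int)
    return SyntheticWorld(dem=dem, coeff_fields=fields, sigma=sigma, beta=beta,
                          years=yr, year0=int(yr[0]), seed=seed,
                          coeff_mode=coeff_mode)


def sample_observations(
    world: SyntheticWorld,
    n_sites: int,
    years: np.ndarray | None = None,
    seed: int = 0,
    *,
    dropout: float = 0.0,
    round_doy: bool = True,
    clip: bool = True,
    phase_id: str = "109-5",
) -> ObservationTable:
    """Draw observer sites on the grid and generate their onset records.

    Sites are drawn uniformly without replacement over unmasked DEM cells;
    each site reports in each year independently with probability
    ``1 - dropout`` (observer attrition).  ``round_doy=False`` keeps the
    exact real-valued plane, which is what exactness checks of the
    downstream pipeline need; the default integer rounding matches the
    day-resolution of real records.
    """
    rng = np.random.default_rng(seed)
    geom = world.geometry
    valid = np.flatnonzero(world.dem.mask.ravel())
    if n_sites > len(valid):
        raise ValueError(f"n_sites={n_sites} exceeds {len(valid)} available cells")
    cells = rng.choice(valid, size=n_sites, replace=False)
    ii, jj = np.unravel_index(cells, geom.shape)
    lats = geom.cell_lats()[ii]
    lons = geom.cell_lons()[jj]
    elevs = world.dem.values[ii, jj]
    a = world.coeff_fields[:, ii, jj]  # (4, n_sites)
    base_doy = a[0] + a[1] * elevs + a[2] * lons + a[3] * lats

    yr = world.years if years is None else np.asarray(years, int)
    rows = []
    n_clipped = 0
    for s in range(n_sites):
        report = rng.random(len(yr)) >= dropout
        noise = rng.normal(0.0, world.sigma, size=len(yr)) if world.sigma > 0 \
            else np.zeros(len(yr))
        doy = base_doy[s] + world.beta * (yr - world.year0) + noise
        if round_doy:
            doy = np.rint(doy)
        if clip:
            n_clipped += int(((doy < 1) | (doy > 366)).sum())
            doy = np.clip(doy, 1, 366)
        for k in np.flatnonzero(report):
            rows.append((f"S{s:04d}", lats[s], lons[s], elevs[s], int(yr[k]),
                         phase_id, doy[k]))
    df = pd.DataFrame(rows, columns=["station_id", "lat", "lon", "elev",
                                     "year", "phase_id", "doy"])
    if round_doy:
        return ObservationTable(df)
    # exactness runs keep float DOY: bypass the integer validation
    return ObservationTable._from_validated(df)


def make_temperature(
    world: SyntheticWorld,
    seed: int = 0,
    *,
    t_mean: float = 9.0,
    t_seasonal_amp: float = 9.0,
    lapse: float = -6.5,        # degC per km of elevation
    year_trend: float = 0.03,   # degC per year
    annual_anomaly_sd: float = 1.2,   # shared across the year's months, degC
    monthly_anomaly_sd: float = 0.8,  # independent per month, degC
) -> TemperatureCube:
    """Monthly 2-m temperature cube over the world's geometry and years.

    T(year, month, cell) = seasonal cycle (peak July) + elevation lapse
    + linear warming + an interannual anomaly shared across cells
    (large-scale weather).  The anomaly has an annual component common to
    all months of a year plus an independent monthly component, mimicking
    the temporal autocorrelation of real monthly temperature anomalies.
    """
    rng = np.random.default_rng(seed)
    geom = world.geometry
    months = np.arange(1, 13)
    cycle = t_mean + t_seasonal_amp * np.cos(2 * np.pi * (months - 7) / 12.0)
    elev_term = lapse * world.dem.values / 1000.0
    years = world.years
    anomalies = (rng.normal(0.0, annual_anomaly_sd, size=(len(years), 1))
                 + rng.normal(0.0, monthly_anomaly_sd, size=(len(years), 12)))
    vals = (
        cycle[None, :, None, None]
        + elev_term[None, None, :, :]
        + (year_trend * (years - years[0]))[:, None, None, None]
        + anomalies[:, :, None, None]
    )
    return TemperatureCube(geom, years, vals)


def _preseason_anomaly_series(cube: TemperatureCube, month: int) -> np.ndarray:
    """Per-year mean anomaly of months (m-2, m-1, m), standardised.

    Years whose window reaches before the cube start reuse the first year's
    month values (a one-off boundary approximation at the series start).
    """
    vals = cube.values.mean(axis=(2, 3))  # (n_years, 12): spatially flat anomaly
    n = len(cube.years)
    out = np.zeros(n)
    for k, _ in enumerate(cube.years):
        acc = 0.0
        for back in range(3):
            mm, ky = month - back, k
            if mm < 1:
                mm += 12
                ky = max(k - 1, 0)
            acc += vals[ky, mm - 1]
        out[k] = acc / 3.0
    out = out - out.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


def make_coupled_onsets(
    world: SyntheticWorld,
    cube: TemperatureCube,
    coupling: float,
    seed: int = 0,
    *,
    onset_sd: float = 5.0,
) -> dict[int, Grid]:
    """Per-year onset grids whose anomalies track preseason temperature.

    The onset anomaly at every cell is a Gaussian mixture
    rho Z + sqrt(1 - rho^2) eps, where Z is the standardised preseason
    (onset month plus two previous) temperature-anomaly series at the
    cell's climatological onset month and rho = ``coupling``.  rho is the
    Pearson correlation of the construction; the implied Spearman
    correlation is (6/pi) asin(rho/2) (see :func:`implied_spearman`).
    Negative coupling encodes a spring phase (warmth advances onset),
    positive an autumn phase.
    """
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    geom = world.geometry
    base = world.true_field()  # climatological surface
    # anchor the coupling month at the mid-series onset so a long-term
    # trend does not sweep cells out of their generating preseason window
    mid_shift = world.beta * (float(np.mean(cube.years)) - world.year0)
    months = doy_to_month(np.where(base.mask, base.values + mid_shift, 182))
    z_by_month = {m: _preseason_anomaly_series(cube, m)
                  for m in np.unique(months[base.mask])}
    n_years = len(cube.years)
    eps = rng.standard_normal((n_years, *geom.shape))
    out: dict[int, Grid] = {}
    resid = np.sqrt(max(1.0 - coupling**2, 0.0))
    for k, year in enumerate(cube.years):
        anom = np.zeros(geom.shape)
        for m, z in z_by_month.items():
            anom[months == m] = coupling * z[k]
        doy = base.values + world.beta * (year - world.year0) \
            + onset_sd * (anom + resid * eps[k])
        g = Grid(geom, doy, base.mask.copy())
        g.year = int(year)  # type: ignore[attr-defined]
        out[int(year)] = g
    return out


def implied_spearman(rho: float) -> float:
    """Spearman correlation implied by a bivariate-Gaussian Pearson rho."""
    return 6.0 / np.pi * np.arcsin(rho / 2.0)


def double_logistic(doy: np.ndarray, base: float, amplitude: float,
                    sos_mid: float, eos_mid: float,
                    rate_up: float = 0.12, rate_down: float = 0.08) -> np.ndarray:
    """Smooth annual NDVI trajectory: green-up and senescence logistics."""
    d = np.asarray(doy, float)
    up = 1.0 / (1.0 + np.exp(-rate_up * (d - sos_mid)))
    down = 1.0 / (1.0 + np.exp(-rate_down * (d - eos_mid)))
    return base + amplitude * (up - down)


def make_ndvi_series(
    sos_true: float,
    eos_true: float,
    *,
    amplitude: float = 0.6,
    base: float = 0.2,
    years: range | tuple[int, int] = (2001, 2019),
    seed: int = 0,
    noise_sd: float = 0.02,
    flag_fraction: float = 0.0,
    missing_fraction: float = 0.0,
    winter_flags_only: bool = False,
    pixel_id: str = "px0",
) -> NdviSeries:
    """Sample a double-logistic annual curve at 23 16-day composites.

    Each composite takes the maximum of the daily curve over its window
    (emulating maximum-value compositing) plus Gaussian radiometric noise.
    ``flag_fraction`` composites are marked cloudy/snow, and
    ``missing_fraction`` are removed outright; with ``winter_flags_only``
    the flags are confined to composites outside April-September.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if not sos_true < eos_true:
        raise ValueError("sos_true must precede eos_true")
    rng = np.random.default_rng(seed)
    if isinstance(years, tuple):
        years = range(years[0], years[1] + 1)
    rows = []
    for year in years:
        for p, d0 in enumerate(COMPOSITE_DOYS):
            window = np.arange(d0, min(d0 + 16, 366))
            clean = double_logistic(window, base, amplitude, sos_true, eos_true).max()
            val = float(np.clip(clean + rng.normal(0.0, noise_sd), -1.0, 1.0))
            code = "good"
            is_winter = d0 < 91 or d0 > 273
            can_flag = is_winter if winter_flags_only else True
            if can_flag and rng.random() < flag_fraction:
                code = "snow" if is_winter and rng.random() < 0.5 else "cloudy"
            if can_flag and rng.random() < missing_fraction:
                code = "missing"
            rows.append((year, p, int(d0),
                         np.nan if code == "missing" else val, code))
    df = pd.DataFrame(rows, columns=["year", "period", "start_doy", "ndvi",
                                     "reliability"])
    return NdviSeries(pixel_id, df)
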