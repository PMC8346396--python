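"""Satellite-side phenology from 16-day NDVI composites.

The extraction chain mirrors standard practice for MOD13Q1-style
vegetation-index products: keep only composites whose pixel-reliability
code is good or marginal, fill remaining gaps with the multi-year mean
annual profile (the climatology), smooth and interpolate to daily
resolution with a LOESS curve, and read the start and end of season (SOS,
EOS) off the smoothed curve at half the seasonal amplitude.

A 365-day year is used throughout (composite start days 1, 17, ..., 353);
at 16-day cadence the leap-day offset is far below the method's
resolution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RELIABILITY_CODES",
    "COMPOSITE_DOYS",
    "NdviSeries",
    "SeasonEstimate",
    "filter_reliability",
    "fill_climatology",
    "loess_smooth",
    "smooth_to_daily",
    "half_amplitude_seasons",
    "extract_seasons",
]

RELIABILITY_CODES = ("good", "marginal", "snow", "cloudy", "missing")
COMPOSITE_DOYS = 1 + 16 * np.arange(23)  # 23 composite start days per year


@dataclass
class NdviSeries:
    """16-day composite NDVI series for one pixel.

    ``df`` columns: year, period (0-22), start_doy, ndvi, reliability.
    NDVI is NaN where flagged missing; finite values lie in [-1, 1].
    """

    pixel_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"year", "period", "start_doy", "ndvi", "reliability"}
        if not req.issubset(self.df.columns):
            raise ValueError(f"NDVI frame must have columns {sorted(req)}")
        df = self.df.sort_values(["year", "period"]).reset_index(drop=True)
        if df.duplicated(["year", "period"]).any():
            raise ValueError("duplicate (year, period) composites")
        bad = ~df["reliability"].isin(RELIABILITY_CODES)
        if bad.any():
            raise ValueError(f"unknown reliability codes: {df.loc[bad, 'reliability'].unique()}")
        finite = df["ndvi"].notna()
        if ((df.loc[finite, "ndvi"] < -1) | (df.loc[finite, "ndvi"] > 1)).any():
            raise ValueError("NDVI values must lie in [-1, 1]")
        self.df = df

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.df["year"].to_numpy())

    def abs_day(self) -> np.ndarray:
        """Days counted from day 1 of the first series year (365-day years)."""
        y0 = int(self.df["year"].min())
        return ((self.df["year"] - y0) * 365 + self.df["start_doy"]).to_numpy(float)

    def copy_with(self, ndvi: np.ndarray) -> "NdviSeries":
        df = self.df.copy()
        df["ndvi"] = ndvi
        return NdviSeries(self.pixel_id, df)


@dataclass
class SeasonEstimate:
    """Half-amplitude season bounds for one pixel-year."""

    year: int
    sos_doy: int | None
    eos_doy: int | None
    threshold: float | None
    reason: str | None = None  # set when no season could be declared

    @property
    def defined(self) -> bool:
        return self.sos_doy is not None and self.eos_doy is not None


def filter_reliability(series: NdviSeries,
                       keep: frozenset = frozenset({"good", "marginal"})) -> NdviSeries:
    """Blank composites whose reliability code is not in ``keep``.

    Values at retained composites are preserved exactly; everything else
    becomes missing (NaN) while the original code column is kept.
    """
    drop = ~series.df["reliability"].isin(keep)
    out = series.copy_with(np.where(drop, np.nan, series.df["ndvi"].to_numpy(float)))
    if out.df["ndvi"].isna().all():
        warnings.warn(f"pixel {series.pixel_id}: no composites survive the "
                      "reliability filter", stacklevel=2)
    return out


def fill_climatology(series: NdviSeries) -> NdviSeries:
    """Fill missing composites with the mean annual profile (climatology).

    For each of the 23 composite positions the climatology is the mean of
    the non-missing values at that position across all years; missing
    entries take that value.  A position missing in every year stays
    missing and is reported.  The operation is idempotent.
    """
    df = series.df
    vals = df["ndvi"].to_numpy(float).copy()
    clim = df.groupby("period")["ndvi"].transform("mean").to_numpy(float)
    missing = np.isnan(vals)
    vals[missing] = clim[missing]
    still = np.isnan(vals)
    if still.any():
        periods = sorted(df.loc[still, "period"].unique())
        logger.warning("pixel %s: composite positions %s missing in every year",
                       series.pixel_id, periods)
    return series.copy_with(vals)


def loess_smooth(t: np.ndarray, y: np.ndarray, t_eval: np.ndarray,
                 q: int) -> np.ndarray:
    """Local quadratic regression with tricube weights (LOESS, degree 2).

    For each evaluation point the bandwidth is the distance to its q-th
    nearest data point; a weighted quadratic is fitted in the local
    coordinate and its value at the origin returned.  The normal equations
    are built for all evaluation points at once, so the cost is one batched
    3x3 solve.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    t_eval = np.asarray(t_eval, float)
    q = int(min(max(q, 3), len(t)))
    d = np.abs(t_eval[:, None] - t[None, :])                      # (D, m)
    h = np.partition(d, q - 1, axis=1)[:, q - 1]
    h = np.maximum(h, 1e-9) * (1 + 1e-9)
    u = np.clip(d / h[:, None], 0.0, 1.0)
    w = (1 - u**3) ** 3
    # local coordinate scaled by the bandwidth: keeps the 3x3 normal
    # equations well-conditioned (raw day offsets to the 4th power are not)
    x = (t[None, :] - t_eval[:, None]) / h[:, None]
    # moments M_k = sum_j w x^k, V_k = sum_j w x^k y, k = 0..4
    M = [np.einsum("dm,dm->d", w, x**k) for k in range(5)]
    V = [np.einsum("dm,dm,m->d", w, x**k, y) for k in range(3)]
    A = np.empty((len(t_eval), 3, 3))
    for i in range(3):
        for j in range(3):
            A[:, i, j] = M[i + j]
    b = np.stack(V, axis=1)
    # tiny ridge keeps near-singular local systems (few distinct points
    # inside the bandwidth) solvable without visibly biasing the fit
    ridge = 1e-12 * (1.0 + A[:, 0, 0] + A[:, 1, 1] + A[:, 2, 2])
    A[:, 0, 0] += ridge
    A[:, 1, 1] += ridge
    A[:, 2, 2] += ridge
    beta = np.linalg.solve(A, b[..., None])
    return beta[:, 0, 0]


def smooth_to_daily(series: NdviSeries, span: float = 0.25) -> pd.DataFrame:
    """LOESS-smooth a composite series and interpolate to daily values.

    ``span`` is the LOESS neighbourhood expressed as a fraction of the 23
    within-year composite positions (default 0.25, i.e. the six nearest
    composites, a window of roughly +/-48 days).  Requires at least 10
    non-missing composites.  Returns a frame with columns year, doy, value
    covering day 1-365 of every series year.
    """
    finite = series.df["ndvi"].notna().to_numpy()
    if finite.sum() < 10:
        raise ValueError(f"pixel {series.pixel_id}: only {int(finite.sum())} "
                         "non-missing composites; need >= 10 to smooth")
    t = series.abs_day()[finite]
    y = series.df["ndvi"].to_numpy(float)[finite]
    years = series.years
    n_days = len(years) * 365
    t_eval = np.arange(1, n_days + 1, dtype=float)
    q = int(np.ceil(span * 23))
    daily = loess_smooth(t, y, t_eval, q)
    return pd.DataFrame({
        "year": np.repeat(years, 365),
        "doy": np.tile(np.arange(1, 366), len(years)),
        "value": daily,
    })


def _crossings(vals: np.ndarray, thr: float) -> tuple[np.ndarray, np.ndarray]:
    """Sub-day upward and downward threshold crossings of a daily curve.

    Day d covers vals[d-1]; a crossing between days d and d+1 is placed by
    linear interpolation.
    """
    below = vals[:-1] < thr
    above_next = vals[1:] >= thr
    up = np.flatnonzero(below & above_next)
    down = np.flatnonzero(~below & ~above_next)
    frac_up = (thr - vals[up]) / (vals[up + 1] - vals[up])
    frac_down = (vals[down] - thr) / (vals[down] - vals[down + 1])
    return (up + 1) + frac_up, (down + 1) + frac_down


def half_amplitude_seasons(daily: pd.DataFrame, year: int,
                           min_amplitude: float = 0.1) -> SeasonEstimate:
    """Season bounds where the daily curve crosses half its annual amplitude.

    threshold = min + 0.5 (max - min) within the calendar year.  SOS is the
    first upward crossing before the day of the annual maximum, EOS the
    last downward crossing after it; crossings are located with sub-day
    linear interpolation and rounded to whole days.  Years whose amplitude
    is below ``min_amplitude`` (default 0.1 NDVI) yield no season — weak or
    absent seasonal cycles do not support a half-amplitude reading.
    """
    sel = daily[daily["year"] == year]
    if sel.empty:
        raise ValueError(f"year {year} not present in daily curve")
    vals = sel["value"].to_numpy(float)
    vmin, vmax = float(vals.min()), float(vals.max())
    amp = vmax - vmin
    if amp < min_amplitude:
        return SeasonEstimate(year, None, None, None, reason="amplitude-below-minimum")
    thr = vmin + 0.5 * amp
    peak = int(np.argmax(vals)) + 1  # DOY of annual maximum
    ups, downs = _crossings(vals, thr)
    ups = ups[ups <= peak]
    downs = downs[downs >= peak]
    if len(ups) == 0 or len(downs) == 0:
        return SeasonEstimate(year, None, None, thr, reason="no-crossing")
    sos = int(round(float(ups[0])))
    eos = int(round(float(downs[-1])))
    return SeasonEstimate(year, sos, eos, thr)


def extract_seasons(series: NdviSeries, span: float = 0.25,
                    min_amplitude: float = 0.1) -> list[SeasonEstimate]:
    """Full pipeline: reliability filter, climatology fill, LOESS, seasons."""
    filtered = filter_reliability(series)
    filled = fill_climatology(filtered)
    daily = smooth_to_daily(filled, span=span)
    return [half_amplitude_seasons(daily, int(y), min_amplitude)
            for y in series.years]
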