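"""Long-term trend and temperature-sensitivity statistics.

Trends of onset-date series are estimated with the Theil-Sen slope (the
median of all pairwise slopes, robust to outlying years) and tested with
the Mann-Kendall test, its conventional significance companion.  The
same machinery runs on two kinds of series: individual observer stations
(subject to record-length filters: at least 30 years, relaxed to 15 for
the winter phase whose record is shorter) and per-cell series extracted
from a stack of yearly interpolated maps.

Temperature sensitivity is the Spearman rank correlation between an
onset series and its preseason mean temperature (the onset month plus
the two preceding months, resolved per year and per cell from that
year's onset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .climate import TemperatureCube, preseason_temperature
from .grids import Grid
from .observations import ObservationTable

logger = logging.getLogger(__name__)

__all__ = [
    "theil_sen",
    "mann_kendall_s",
    "trend_significance",
    "TrendResult",
    "TrendSummary",
    "trend_map",
    "spearman",
    "preseason_series",
    "correlation_map",
]


def theil_sen(years, doys) -> float:
    """Theil-Sen slope: median of all pairwise slopes, in days per year."""
    x = np.asarray(years, float)
    y = np.asarray(doys, float)
    if len(np.unique(x)) < 2:
        raise ValueError("Theil-Sen slope undefined: fewer than two distinct years")
    return float(stats.theilslopes(y, x).slope)


def mann_kendall_s(years, doys) -> int:
    """Mann-Kendall S statistic: concordant minus discordant pairs (in
    time order), ties contributing zero."""
    x = np.asarray(years, float)
    y = np.asarray(doys, float)
    order = np.argsort(x, kind="stable")
    y = y[order]
    s = 0
    for i, j in combinations(range(len(y)), 2):
        s += int(np.sign(y[j] - y[i]))
    return s


def trend_significance(years, doys) -> float:
    """Two-sided Mann-Kendall p-value.

    Uses the tie-corrected variance with continuity correction under the
    normal approximation for n > 10; for small tie-free samples the exact
    null distribution of Kendall's S is used (via the exact tau test,
    which is the same statistic).  Ties in the year axis are not supported
    here — average duplicate years first.
    """
    x = np.asarray(years, float)
    y = np.asarray(doys, float)
    n = len(y)
    if n < 3:
        raise ValueError("Mann-Kendall needs at least 3 points")
    if len(np.unique(x)) != n:
        raise ValueError("duplicate years: aggregate before testing")
    _, counts = np.unique(y, return_counts=True)
    has_ties = np.any(counts > 1)
    if n <= 10 and not has_ties:
        return float(stats.kendalltau(x, y, method="exact").pvalue)
    s = mann_kendall_s(x, y)
    var = n * (n - 1) * (2 * n + 5) / 18.0
    var -= np.sum(counts * (counts - 1) * (2 * counts + 5)) / 18.0
    if var <= 0:
        return 1.0
    z = (s - np.sign(s)) / np.sqrt(var)  # continuity correction
    return float(2.0 * stats.norm.sf(abs(z)))


def _mk_p_batch(y: np.ndarray) -> np.ndarray:
    """Vectorised Mann-Kendall p-values for row-wise series at a common,
    strictly increasing time axis (normal approximation)."""
    n = y.shape[1]
    sign = np.sign(y[:, None, :] - y[:, :, None])  # (m, n, n)
    iu = np.triu_indices(n, 1)
    s = sign[:, iu[0], iu[1]].sum(axis=1)
    var = np.full(y.shape[0], n * (n - 1) * (2 * n + 5) / 18.0)
    for r in range(y.shape[0]):  # tie correction per series
        _, counts = np.unique(y[r], return_counts=True)
        ties = counts[counts > 1]
        if ties.size:
            var[r] -= np.sum(ties * (ties - 1) * (2 * ties + 5)) / 18.0
    z = np.where(var > 0, (s - np.sign(s)) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    return 2.0 * stats.norm.sf(np.abs(z))


@dataclass
class TrendResult:
    series_id: str
    slope: float
    p_value: float
    n_years: int


@dataclass
class TrendSummary:
    """Distribution summary in the style of per-phase trend panels."""

    mean_slope: float
    sd_slope: float
    n_series: int
    prop_sig_negative: float  # significant negative / all negative
    prop_sig_positive: float  # significant positive / all positive

    @classmethod
    def from_results(cls, results: list[TrendResult],
                     alpha: float = 0.05) -> "TrendSummary":
        if not results:
            raise ValueError("no trend results to summarise")
        slopes = np.array([r.slope for r in results])
        ps = np.array([r.p_value for r in results])
        neg = slopes < 0
        pos = slopes > 0
        return cls(
            mean_slope=float(slopes.mean()),
            sd_slope=float(slopes.std()),
            n_series=len(results),
            prop_sig_negative=float((ps[neg] < alpha).mean()) if neg.any() else np.nan,
            prop_sig_positive=float((ps[pos] < alpha).mean()) if pos.any() else np.nan,
        )


def trend_map(
    grid_stack: dict[int, Grid] | None = None,
    station_table: ObservationTable | None = None,
    *,
    min_years: int = 30,
    winter_phase: bool = False,
    max_grid_series: int | None = None,
    seed: int = 0,
) -> dict[str, tuple[list[TrendResult], TrendSummary | None]]:
    """Theil-Sen trends for interpolated grid cells and/or station series.

    Grid cells are treated as individual time series over the stack's
    years; stations enter only with at least ``min_years`` of data
    (15 instead of 30 when ``winter_phase``).  ``max_grid_series`` draws a
    reproducible random subset of cells for large grids.
    Returns ``{"interpol": (results, summary), "obs": (...)}`` for the
    parts that were supplied; empty inputs yield ``([], None)``.
    """
    out: dict[str, tuple[list[TrendResult], TrendSummary | None]] = {}
    if grid_stack is not None:
        years = np.array(sorted(grid_stack))
        mask = np.logical_and.reduce([grid_stack[y].mask for y in years])
        cells = np.flatnonzero(mask.ravel())
        if max_grid_series is not None and len(cells) > max_grid_series:
            rng = np.random.default_rng(seed)
            cells = np.sort(rng.choice(cells, max_grid_series, replace=False))
        series = np.stack([grid_stack[y].values.ravel()[cells] for y in years],
                          axis=1)  # (n_cells, n_years)
        ps = _mk_p_batch(series) if series.shape[0] else np.empty(0)
        results = []
        for r, cell in enumerate(cells):
            slope = theil_sen(years, series[r])
            results.append(TrendResult(f"cell{cell}", slope, float(ps[r]),
                                       len(years)))
        summary = TrendSummary.from_results(results) if results else None
        out["interpol"] = (results, summary)
    if station_table is not None:
        need = 15 if winter_phase else min_years
        results = []
        n_excluded = 0
        for sid, s in station_table.station_series().items():
            if len(s) < need:
                n_excluded += 1
                continue
            slope = theil_sen(s["year"], s["doy"])
            p = trend_significance(s["year"], s["doy"])
            results.append(TrendResult(sid, slope, p, len(s)))
        if n_excluded:
            logger.info("trend filter: excluded %d stations with < %d years",
                        n_excluded, need)
        summary = TrendSummary.from_results(results) if results else None
        out["obs"] = (results, summary)
    return out


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length series of at least 3 points")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman undefined: zero rank variance")
    return float(stats.spearmanr(x, y).statistic)


def preseason_series(cube: TemperatureCube, onset_stack: dict[int, Grid],
                     climatological_months: bool = False) -> dict[int, Grid]:
    """Per-year preseason-temperature grids matched to an onset stack.

    With ``climatological_months`` the window of every cell is fixed at
    the month of its multi-year mean onset instead of varying with each
    year's onset.
    """
    month_source = None
    if climatological_months:
        years = sorted(onset_stack)
        mean_onset = np.nanmean(
            np.stack([onset_stack[y].values for y in years]), axis=0)
        mask = np.logical_and.reduce([onset_stack[y].mask for y in years])
        month_source = Grid(onset_stack[years[0]].geometry, mean_onset, mask)
    out = {}
    for year, g in sorted(onset_stack.items()):
        g = _with_year(g, year)
        out[year] = preseason_temperature(cube, g, month_source)
    return out


def _with_year(grid: Grid, year: int) -> Grid:
    grid.year = year  # type: ignore[attr-defined]
    return grid


def correlation_map(
    onset_stack: dict[int, Grid],
    cube: TemperatureCube,
    *,
    station_table: ObservationTable | None = None,
    min_overlap: int = 10,
    max_cells: int | None = None,
    seed: int = 0,
    climatological_months: bool = False,
) -> dict[str, pd.DataFrame]:
    """Spearman correlation of onset vs preseason temperature.

    For the interpolated product every grid cell yields one correlation
    over the years where both onset and preseason temperature exist; for
    stations (``"obs"``) each station is paired with its nearest grid
    cell's temperature series.  Series with fewer than ``min_overlap``
    usable years are skipped and counted.  ``climatological_months``
    fixes each cell's preseason window at its mean-onset month (see
    :func:`preseason_series`).
    """
    pres = preseason_series(cube, onset_stack, climatological_months)
    years = np.array(sorted(onset_stack))
    geom = cube.geometry
    onset_arr = np.stack([onset_stack[y].values.ravel() for y in years])
    pres_arr = np.stack([pres[y].values.ravel() for y in years])
    valid = np.isfinite(onset_arr) & np.isfinite(pres_arr)
    enough = valid.sum(axis=0) >= min_overlap
    cells = np.flatnonzero(enough)
    if max_cells is not None and len(cells) > max_cells:
        rng = np.random.default_rng(seed)
        cells = np.sort(rng.choice(cells, max_cells, replace=False))
    rows = []
    for cell in cells:
        ok = valid[:, cell]
        try:
            rho = spearman(onset_arr[ok, cell], pres_arr[ok, cell])
        except ValueError:
            continue
        rows.append({"series_id": f"cell{cell}", "rho": rho,
                     "n_years": int(ok.sum())})
    out = {"interpol": pd.DataFrame(rows, columns=["series_id", "rho", "n_years"])}

    if station_table is not None:
        rows = []
        n_skipped = 0
        for sid, s in station_table.station_series().items():
            st = station_table.df[station_table.df.station_id == sid].iloc[0]
            i, j = geom.nearest_cell(float(st.lat), float(st.lon))
            cell = i * geom.ncols + j
            merged = s[s.year.isin(years)]
            ok_years, onset_vals, temp_vals = [], [], []
            for _, row in merged.iterrows():
                k = int(np.searchsorted(years, row.year))
                t = pres_arr[k, cell]
                if np.isfinite(t):
                    ok_years.append(row.year)
                    onset_vals.append(row.doy)
                    temp_vals.append(t)
            if len(ok_years) < min_overlap:
                n_skipped += 1
                continue
            try:
                rho = spearman(onset_vals, temp_vals)
            except ValueError:
                n_skipped += 1
                continue
            rows.append({"series_id": sid, "rho": rho, "n_years": len(ok_years)})
        if n_skipped:
            logger.info("correlation: skipped %d stations (insufficient overlap)",
                        n_skipped)
        out["obs"] = pd.DataFrame(rows, columns=["series_id", "rho", "n_years"])
    return out
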