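"""Monthly temperature cubes and preseason-temperature extraction.

The preseason of an onset date is the calendar month containing the onset
plus the two preceding months; for onsets in January or February the
window reaches into the previous calendar year.  Phenological onsets of
spring phases are expected to correlate negatively with their preseason
mean temperature (warm springs advance onset), autumn phases positively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Grid, GridGeometry

__all__ = ["TemperatureCube", "doy_to_month", "preseason_temperature"]

# first DOY of each month in a non-leap year; month 13 sentinel = 366
_MONTH_STARTS = np.array([1, 32, 60, 91, 121, 152, 182, 213, 244, 274, 305, 335, 367])


def doy_to_month(doy) -> np.ndarray:
    """Calendar month (1-12) containing a day of year (non-leap convention;
    DOY 366 counts as December)."""
    d = np.clip(np.asarray(doy), 1, 366)
    return np.searchsorted(_MONTH_STARTS, d, side="right").astype(int)


@dataclass
class TemperatureCube:
    """Mean monthly 2-m air temperature on the interpolation geometry.

    ``values`` has shape (n_years, 12, nrows, ncols) in degrees Celsius;
    ``years`` is the contiguous year range covered.
    """

    geometry: GridGeometry
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.years), 12, *self.geometry.shape):
            raise ValueError("temperature cube shape must be (years, 12, nrows, ncols)")
        if len(self.years) > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("year range must be contiguous")

    def monthly(self, year: int, month: int) -> np.ndarray:
        if not 1 <= month <= 12:
            raise ValueError(f"month {month} out of range")
        iy = int(np.searchsorted(self.years, year))
        if iy >= len(self.years) or self.years[iy] != year:
            raise KeyError(f"year {year} not in cube")
        return self.values[iy, month - 1]


def preseason_temperature(cube: TemperatureCube, onset: Grid,
                          month_source: Grid | None = None) -> Grid:
    """Mean temperature of the onset month and the two months before it.

    ``onset`` is a per-cell onset-DOY grid for one year; the year is taken
    from ``onset.year`` set by the caller, falling back to the last cube
    year.  Cells whose window reaches before the first cube year are
    masked.

    By default the window is resolved per year from that year's onset.
    Passing ``month_source`` (typically the multi-year mean onset grid)
    fixes each cell's window at its climatological onset month instead —
    the per-year window mixes different seasonal baselines for cells whose
    onsets straddle a calendar-month boundary, which dilutes correlation
    estimates there.
    """
    year = getattr(onset, "year", int(cube.years[-1]))
    if onset.geometry != cube.geometry:
        raise ValueError("onset grid geometry does not match the cube")
    src = onset if month_source is None else month_source
    months = doy_to_month(np.where(src.mask, src.values, 6))
    out = np.full(onset.geometry.shape, np.nan)
    mask = onset.mask.copy()
    for m in range(1, 13):
        cells = onset.mask & (months == m)
        if not cells.any():
            continue
        acc = np.zeros(onset.geometry.shape)
        ok = True
        for back in range(3):
            mm, yy = m - back, year
            if mm < 1:
                mm += 12
                yy -= 1
            if yy < cube.years[0] or yy > cube.years[-1]:
                ok = False
                break
            acc += cube.monthly(yy, mm)
        if ok:
            out[cells] = acc[cells] / 3.0
        else:
            mask[cells] = False
    return Grid(onset.geometry, out, mask)
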