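"""Phenological observation tables.

An observation is one onset date: a station (with coordinates and
elevation), a year, a phenophase identifier such as ``"109-5"``, and the
onset day of year (DOY, 1-366).  Tables are long-format pandas DataFrames
validated on construction; (station_id, phase_id, year) is unique.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["COLUMNS", "ObservationTable", "read_observations", "write_observations"]

COLUMNS = ["station_id", "lat", "lon", "elev", "year", "phase_id", "doy"]


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class ObservationTable:
    """Validated long-format table of phenological onset records.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain the columns ``station_id, lat, lon, elev, year,
        phase_id, doy``.  Rows violating the invariants (DOY outside
        1-366, non-finite coordinates, negative elevation) raise unless
        ``drop_invalid`` is set, in which case they are dropped and
        counted.
    allow_below_sea_level : bool
        Permit negative elevations (coastal stations below NHN).
    """

    def __init__(self, df: pd.DataFrame, *, drop_invalid: bool = False,
                 allow_below_sea_level: bool = False):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = df.loc[:, COLUMNS].copy()
        df["station_id"] = df["station_id"].astype(str)
        df["phase_id"] = df["phase_id"].astype(str)
        for col in ("lat", "lon", "elev", "doy"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df["year"] = pd.to_numeric(df["year"], errors="coerce")

        ok = (
            df[["lat", "lon", "elev", "year", "doy"]].notna().all(axis=1)
            & np.isfinite(df["lat"])
            & np.isfinite(df["lon"])
            & np.isfinite(df["elev"])
            & df["doy"].between(1, 366)
            & (df["doy"] == df["doy"].round())
            & (df["year"] == df["year"].round())
        )
        if not allow_below_sea_level:
            ok &= df["elev"] >= 0
        bad_idx = df.index[~ok]
        if len(bad_idx) and not drop_invalid:
            raise ValueError(
                f"{len(bad_idx)} invalid rows (first offenders at input rows "
                f"{list(bad_idx[:5])}); pass drop_invalid=True to drop them"
            )
        if len(bad_idx):
            logger.warning("dropped %d invalid observation rows: %s%s",
                           len(bad_idx), list(bad_idx[:10]),
                           "..." if len(bad_idx) > 10 else "")
        df = df.loc[ok].copy()
        df["year"] = df["year"].astype(int)
        df["doy"] = df["doy"].astype(int)

        dup = df.duplicated(subset=["station_id", "phase_id", "year"], keep=False)
        if dup.any():
            key = df.loc[dup, ["station_id", "phase_id", "year"]].iloc[0]
            raise ValueError(
                "duplicate (station_id, phase_id, year) key, e.g. "
                f"({key.station_id!r}, {key.phase_id!r}, {int(key.year)})"
            )
        self.df = df.reset_index(drop=True)
        self.n_rejected = int(len(bad_idx))

    @classmethod
    def _from_validated(cls, df: pd.DataFrame) -> "ObservationTable":
        """Rewrap an already-validated frame (row subsets, float-DOY
        synthetic tables) without re-running the integer-DOY checks."""
        table = cls.__new__(cls)
        table.df = df.reset_index(drop=True)
        table.n_rejected = 0
        return table

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (f"ObservationTable({len(self)} records, "
                f"{self.df.station_id.nunique()} stations, "
                f"{self.df.phase_id.nunique()} phases)")

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (lat, lon)."""
        return self.df[["lat", "lon"]].to_numpy(float)

    def select(self, phase_id: str | None = None, year: int | None = None) -> "ObservationTable":
        df = self.df
        if phase_id is not None:
            df = df[df.phase_id == phase_id]
        if year is not None:
            df = df[df.year == year]
        return ObservationTable._from_validated(df.copy())

    def subset(self, index) -> "ObservationTable":
        return ObservationTable._from_validated(self.df.iloc[np.asarray(index)].copy())

    def design_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, y) for the onset model DOY ~ 1 + elev + lon + lat."""
        X = np.column_stack([
            np.ones(len(self.df)),
            self.df["elev"].to_numpy(float),
            self.df["lon"].to_numpy(float),
            self.df["lat"].to_numpy(float),
        ])
        return X, self.df["doy"].to_numpy(float)

    def station_series(self, min_years: int = 1) -> dict[str, pd.DataFrame]:
        """Per-station (year, doy) series with at least ``min_years`` entries.

        Duplicate years (same station observed twice across phases is not
        possible within one phase; duplicates can only enter via merged
        tables) are averaged before trend fitting.
        """
        out: dict[str, pd.DataFrame] = {}
        for sid, g in self.df.groupby("station_id"):
            s = g.groupby("year", as_index=False)["doy"].mean()
            if len(s) >= min_years:
                out[sid] = s
        return out


def read_observations(path: str | Path, schema: dict[str, str] | None = None,
                      *, drop_invalid: bool = True, sep: str = ",") -> ObservationTable:
    """Read a delimited observation file into a validated table.

    ``schema`` maps the canonical column names to the file's header names,
    e.g. ``{"station_id": "Stations_id", "doy": "Jultag"}``; unmapped
    canonical names are assumed to appear verbatim.  Invalid rows are
    dropped with a logged warning (kept + rejected always sums to the
    input row count); duplicate keys are an error.
    """
    raw = pd.read_csv(path, sep=sep)
    schema = schema or {}
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: cannot map required columns {missing}")
    table = ObservationTable(raw, drop_invalid=drop_invalid)
    logger.info("read %d observations from %s (%d rejected)",
                len(table), path, table.n_rejected)
    return table


def write_observations(table: ObservationTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)
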