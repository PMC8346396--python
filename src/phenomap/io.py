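"""Raster and table I/O for grids.

The raster format is the ESRI ASCII grid (``.asc``): a plain-text header
(ncols, nrows, xllcorner/xllcenter, yllcorner/yllcenter, cellsize,
NODATA_value) followed by rows of values north to south.  Grids can also
be written as long-format CSV (lat, lon, value) with masked cells omitted.
Round-trips are value-exact to float precision.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import DemGrid, Grid, GridGeometry

logger = logging.getLogger(__name__)

__all__ = ["read_dem", "read_grid", "write_grid"]

_DEFAULT_NODATA = -9999.0


def _parse_ascii_grid(path: Path) -> tuple[GridGeometry, np.ndarray, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: empty or truncated raster")
            parts = line.split()
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float, ndmin=2)

    for key in ("ncols", "nrows"):
        if key not in header:
            raise ValueError(f"{path}: missing required header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if "cellsize" in header:
        dx = dy = header["cellsize"]
    elif "dx" in header and "dy" in header:  # GDAL AAIGrid extension
        dx, dy = header["dx"], header["dy"]
    else:
        raise ValueError(f"{path}: missing cellsize (or dx/dy)")
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({nrows}, {ncols})")
    if "xllcenter" in header:
        west = header["xllcenter"]
    elif "xllcorner" in header:
        west = header["xllcorner"] + dx / 2
    else:
        raise ValueError(f"{path}: missing xllcorner/xllcenter")
    if "yllcenter" in header:
        south = header["yllcenter"]
    elif "yllcorner" in header:
        south = header["yllcorner"] + dy / 2
    else:
        raise ValueError(f"{path}: missing yllcorner/yllcenter")
    north = south + (nrows - 1) * dy
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    geom = GridGeometry(north=north, west=west, dlat=dy, dlon=dx,
                        nrows=nrows, ncols=ncols)
    return geom, data, nodata


def read_dem(path: str | Path) -> DemGrid:
    """Read a single-band ESRI ASCII raster as a DEM; nodata becomes mask."""
    geom, data, nodata = _parse_ascii_grid(Path(path))
    mask = data != nodata
    values = np.where(mask, data, np.nan)
    dem = DemGrid(geom, values, mask)
    logger.info("read DEM %s: %dx%d, %d valid cells", path, geom.nrows,
                geom.ncols, dem.n_valid)
    return dem


def read_grid(path: str | Path) -> Grid:
    """Read any single-layer ASCII raster as a generic grid."""
    geom, data, nodata = _parse_ascii_grid(Path(path))
    mask = data != nodata
    return Grid(geom, np.where(mask, data, np.nan), mask)


def write_grid(grid: Grid, path: str | Path, fmt: str = "raster",
               nodata: float = _DEFAULT_NODATA) -> None:
    """Write a grid as an ASCII raster (``fmt="raster"``) or long CSV.

    The CSV layout is one row per valid cell: ``lat, lon, value`` — masked
    cells are omitted.  A fully masked grid produces an empty table with a
    warning.
    """
    path = Path(path)
    geom = grid.geometry
    if fmt == "raster":
        out = np.where(grid.mask, grid.values, nodata)
        if np.isclose(geom.dlat, geom.dlon):
            size_lines = f"cellsize {geom.dlat!r}\n"
        else:  # GDAL AAIGrid dx/dy extension for rectangular cells
            size_lines = f"dx {geom.dlon!r}\ndy {geom.dlat!r}\n"
        header = (
            f"ncols {geom.ncols}\n"
            f"nrows {geom.nrows}\n"
            f"xllcenter {geom.west!r}\n"
            f"yllcenter {geom.north - (geom.nrows - 1) * geom.dlat!r}\n"
            + size_lines
            + f"NODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")
    elif fmt == "table":
        lat2, lon2 = geom.cell_centers()
        if grid.n_valid == 0:
            warnings.warn(f"writing empty table to {path}: all cells masked",
                          stacklevel=2)
        pd.DataFrame({
            "lat": lat2[grid.mask],
            "lon": lon2[grid.mask],
            "value": grid.values[grid.mask],
        }).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    logger.info("wrote %s grid (%s) to %s", fmt, grid.geometry.shape, path)
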