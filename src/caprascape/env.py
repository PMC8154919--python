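"""Environmental layers: gridded variables, terrain slope, point extraction,
and iterative reduction of correlated bioclimatic variables.

Grids use the ESRI ASCII raster dialect (6-line header: ncols, nrows,
xllcorner, yllcorner, cellsize, nodata_value) with row 0 of the value block
being the northernmost row.  Extraction is nearest-cell, no interpolation,
matching how point values are pulled from 2.5-arcminute bioclimatic
rasters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class GridError(ValueError):
    pass


@dataclass
class EnvGrid:
    """A regular lat/lon grid of one variable; values[0] is the top row."""

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise GridError("grid must be a nonempty 2-D array")
        if self.cellsize <= 0:
            raise GridError("cellsize must be > 0")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of a cell center; row 0 is the northernmost row."""
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - row - 0.5) * self.cellsize
        return lat, lon


def read_ascii_grid(path: str | Path) -> EnvGrid:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    for line in lines[:6]:
        k, v = line.split()
        hdr[k.lower()] = float(v)
    values = np.loadtxt(lines[6:]).reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    values[values == hdr.get("nodata_value", -9999.0)] = np.nan
    return EnvGrid(values, hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"],
                   hdr.get("nodata_value", -9999.0))


def write_ascii_grid(grid: EnvGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll}\n")
        fh.write(f"yllcorner {grid.yll}\n")
        fh.write(f"cellsize {grid.cellsize}\n")
        fh.write(f"nodata_value {grid.nodata}\n")
        vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
        np.savetxt(fh, vals, fmt="%.6g")


def extract_at_points(grid: EnvGrid, latitudes, longitudes) -> np.ndarray:
    """Nearest-cell value at each (lat, lon); NaN with a warning out of bounds."""
    lat = np.atleast_1d(np.asarray(latitudes, dtype=float))
    lon = np.atleast_1d(np.asarray(longitudes, dtype=float))
    col = np.floor((lon - grid.xll) / grid.cellsize).astype(int)
    row = np.floor((grid.yll + grid.nrows * grid.cellsize - lat) / grid.cellsize).astype(int)
    out = np.full(lat.shape, np.nan)
    inside = (col >= 0) & (col < grid.ncols) & (row >= 0) & (row < grid.nrows)
    if (~inside).any():
        warnings.warn(f"{int((~inside).sum())} point(s) outside grid bounds; value absent")
    out[inside] = grid.values[row[inside], col[inside]]
    return out


def slope_from_elevation(grid: EnvGrid, cell_length_m: float | None = None) -> EnvGrid:
    """Terrain slope in degrees by Horn's eight-neighbour gradient.

    ``cell_length_m`` is the physical edge length of one cell in the same
    units as elevation (defaults to ``cellsize``, i.e. a projected grid).
    Border cells are absent (NaN).
    """
    if grid.nrows < 3 or grid.ncols < 3:
        raise GridError("slope needs at least a 3x3 grid")
    cs = cell_length_m if cell_length_m is not None else grid.cellsize
    z = grid.values
    slope = np.full_like(z, np.nan)
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                   f = z[1:-1, 2:]
    g_ = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g_)) / (8.0 * cs)
    dzdy = ((g_ + 2 * h + i) - (a + 2 * b + c)) / (8.0 * cs)
    slope[1:-1, 1:-1] = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return EnvGrid(slope, grid.xll, grid.yll, grid.cellsize, grid.nodata)


def reduce_correlated(
    table: pd.DataFrame,
    threshold: float = 0.7,
    seed: int = 0,
    on: str = "r2",
) -> tuple[list[str], dict[str, str]]:
    """Iteratively drop one of the two most correlated variables.

    ``table`` holds one row per unit (breed or individual) and one column
    per variable.  While the maximum pairwise squared Pearson correlation
    (or |r| with ``on="r"``) is at or above ``threshold``, one member of the
    top pair is removed at random (seeded).  Returns the retained variables
    plus a map from each removed variable to its retained proxy.
    """
    if on not in ("r", "r2"):
        raise ValueError("on must be 'r' or 'r2'")
    cols = [c for c in table.columns]
    if len(cols) < 2:
        raise ValueError("need at least 2 variables")
    data = table.dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete units")
    rng = np.random.default_rng(seed)
    retained = list(cols)
    excluded: dict[str, str] = {}
    while len(retained) >= 2:
        corr = data[retained].corr().to_numpy()
        stat = corr ** 2 if on == "r2" else np.abs(corr)
        np.fill_diagonal(stat, 0.0)
        idx = np.unravel_index(np.nanargmax(stat), stat.shape)
        if stat[idx] < threshold:
            break
        pair = (retained[idx[0]], retained[idx[1]])
        drop = pair[int(rng.integers(2))]
        keep = pair[0] if drop == pair[1] else pair[1]
        retained.remove(drop)
        excluded[drop] = keep
    # re-point proxies that were themselves removed later
    for k in list(excluded):
        while excluded[k] in excluded:
            excluded[k] = excluded[excluded[k]]
    return retained, excluded


def env_wide(env_long: pd.DataFrame, epoch: str = "current") -> pd.DataFrame:
    """Pivot a long env table (unit_id, variable, epoch, value) to units x variables."""
    sub = env_long[env_long["epoch"] == epoch]
    return sub.pivot(index="unit_id", columns="variable", values="value")
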