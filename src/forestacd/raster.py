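"""Regular-grid rasters for elevation and canopy-height surfaces.

A :class:`GridRaster` is the carrier for the DEM (bare ground), DSM (top
surface) and CHM (canopy height) produced by the point-cloud pipeline.
Conventions: the origin is the minimum-x/minimum-y corner of the grid,
row 0 is the northernmost row (max y), and nodata is represented as NaN
in memory. On disk rasters are stored as single-band ESRI ASCII grids
(plain text), which round-trip the origin, cell size and nodata marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA_DEFAULT = -9999.0


@dataclass
class GridRaster:
    """A north-up regular grid of float values in metres.

    Parameters
    ----------
    origin : (float, float)
        World coordinates of the min-x/min-y (lower-left) corner.
    cell_size : float
        Edge length of a square cell, metres.
    values : ndarray, shape (nrows, ncols)
        Cell values; NaN marks nodata. Row 0 is the max-y row.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded area."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of every cell center as two (nrows, ncols) arrays."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def world_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map world coordinates to (row, col) indices (may fall outside the grid)."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = self.nrows - 1 - np.floor((np.asarray(y) - y0) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 + (self.nrows - row - 0.5) * self.cell_size)

    def finite_values(self) -> np.ndarray:
        """All non-nodata cell values as a flat array."""
        v = self.values.ravel()
        return v[np.isfinite(v)]

    def copy_with(self, values: np.ndarray) -> "GridRaster":
        return GridRaster(origin=self.origin, cell_size=self.cell_size, values=values)

    # ------------------------------------------------------------------ I/O

    def write_ascii(self, path: str | Path, nodata: float = NODATA_DEFAULT) -> None:
        """Write as an ESRI ASCII grid (text, single band)."""
        out = np.where(np.isfinite(self.values), self.values, nodata)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {float(self.origin[0])!r}\n"
            f"yllcorner {float(self.origin[1])!r}\n"
            f"cellsize {float(self.cell_size)!r}\n"
            f"NODATA_value {float(nodata)!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.6f")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "GridRaster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)
        nodata = meta.get("nodata_value", NODATA_DEFAULT)
        values[values == nodata] = np.nan
        return cls(
            origin=(meta["xllcorner"], meta["yllcorner"]),
            cell_size=meta["cellsize"],
            values=values,
        )
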