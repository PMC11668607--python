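"""Regular raster grids and plain-text raster I/O.

Convention (fixed): axis-aligned grid, row-major values, origin at the
UPPER-LEFT corner; row 0 is the northernmost row. Prediction locations
are cell centers. Grids are written as ESRI ASCII grids (.asc), an open
text format readable by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterGrid", "write_ascii_grid", "read_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-variable regular grid in planar meter coordinates."""

    origin_x: float  # x of the upper-left corner
    origin_y: float  # y of the upper-left corner (max y)
    cell_size_m: float
    values: np.ndarray  # shape (n_rows, n_cols); np.nan marks nodata
    nodata: float = DEFAULT_NODATA
    variable: str = ""

    def __post_init__(self) -> None:
        if not self.cell_size_m > 0:
            raise ValueError("cell_size_m must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edge."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size_m,
            self.origin_x + self.n_cols * self.cell_size_m,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (x, y) of all cell centers, shape (n_rows, n_cols)."""
        cs = self.cell_size_m
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * cs
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing points (x, y).

        Points exactly on the outer boundary belong to the edge cell;
        no bounds check beyond that clamping.
        """
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size_m).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size_m).astype(int)
        return (
            np.clip(row, 0, self.n_rows - 1),
            np.clip(col, 0, self.n_cols - 1),
        )

    def contains(self, x, y) -> np.ndarray:
        """True for points inside the closed grid extent."""
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def value_at(self, x, y) -> np.ndarray:
        """Nearest-cell (containing-cell) lookup; NaN outside the grid."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.full(x.shape, np.nan)
        inside = self.contains(x, y)
        row, col = self.index_of(x[inside], y[inside])
        out[inside] = self.values[row, col]
        return out


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid; NaN cells become the nodata marker."""
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    xmin, ymin, _, _ = grid.extent
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {xmin!r}\n"
        f"yllcorner {ymin!r}\n"
        f"cellsize {grid.cell_size_m!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path, variable: str = "") -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values[values == nodata] = np.nan
    cs = header["cellsize"]
    return RasterGrid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + header["nrows"] * cs,
        cell_size_m=cs,
        values=values,
        nodata=nodata,
        variable=variable,
    )
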