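"""Georeferenced raster grid.

A :class:`Grid` is the carrier for every raster in the pipeline: elevation,
landcover classes, per-layer and cumulative resistance, and current density.
Coordinates are in a projected CRS in metres; the origin is the top-left cell
*corner*; cells are addressed ``(row, col)``, 0-based, row 0 at the top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Grid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Grid:
    """A single-band raster with an explicit nodata mask.

    Parameters
    ----------
    data
        2-D array of cell values. Values under the mask are ignored.
    cell_size
        Edge length of a (square) cell in metres.
    origin
        ``(x, y)`` of the top-left cell corner in CRS coordinates.
    crs
        Identifier of the projected CRS; purely informational.
    nodata_mask
        Boolean array, True where the cell carries no data.
    """

    data: np.ndarray
    cell_size: float = 150.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "local-metric"
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("grid data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.data.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.data.shape:
                raise ValueError("nodata mask shape mismatch")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        """(x, y) of cell centres; y decreases with increasing row."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Containing cell of a point; no bounds check."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains_rowcol(self, row, col) -> np.ndarray:
        nr, nc = self.shape
        return (np.asarray(row) >= 0) & (np.asarray(row) < nr) & \
            (np.asarray(col) >= 0) & (np.asarray(col) < nc)

    # -- helpers ----------------------------------------------------------
    def copy(self) -> "Grid":
        return replace(self, data=self.data.copy(),
                       nodata_mask=self.nodata_mask.copy())

    def like(self, data: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """New grid sharing this grid's georeferencing."""
        return Grid(data, self.cell_size, self.origin, self.crs,
                    self.nodata_mask.copy() if mask is None else mask)

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.data, mask=self.nodata_mask)

    def valid_values(self) -> np.ndarray:
        return self.data[~self.nodata_mask]


_NODATA = -9999.0


def write_ascii_grid(grid: Grid, path) -> None:
    """Write a grid as an ESRI ASCII raster (plain text)."""
    nrows, ncols = grid.shape
    x0, ytop = grid.origin
    yll = ytop - nrows * grid.cell_size
    data = np.asarray(grid.data, dtype=float).copy()
    data[grid.nodata_mask] = _NODATA
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {x0:.6f}\nyllcorner {yll:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\nNODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.8g")


def read_ascii_grid(path, crs: str = "local-metric") -> Grid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    nodata = header.get("nodata_value", _NODATA)
    mask = data == nodata
    return Grid(data, cell, origin, crs, mask)
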