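"""Planar raster grid shared by every raster in an analysis.

All spatial data live on one template grid: a rectangular array of square
cells (30 m by default) in a single projected CRS, coordinates in meters.
Row 0 is the southernmost row, so ``y`` increases with the row index;
array values are addressed ``[row, col]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import box


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster template.

    Parameters
    ----------
    x0, y0
        Coordinates of the grid's south-west corner (meters).
    cell
        Cell side length in meters (square cells).
    nrows, ncols
        Array shape.
    crs
        Label of the projected CRS; informational only — all math is planar.
    """

    x0: float
    y0: float
    cell: float
    nrows: int
    ncols: int
    crs: str = "EPSG:32612"

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    # -- extent ------------------------------------------------------------
    @property
    def width(self) -> float:
        return self.ncols * self.cell

    @property
    def height(self) -> float:
        return self.nrows * self.cell

    @property
    def xmax(self) -> float:
        return self.x0 + self.width

    @property
    def ymax(self) -> float:
        return self.y0 + self.height

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def extent_polygon(self):
        """Grid footprint as a shapely box."""
        return box(self.x0, self.y0, self.xmax, self.ymax)

    # -- centers -----------------------------------------------------------
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.nrows) + 0.5) * self.cell

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, shape (nrows, ncols)."""
        xs = self.x_centers()
        ys = self.y_centers()
        return np.meshgrid(xs, ys)

    # -- point <-> cell ----------------------------------------------------
    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x0) & (x < self.xmax) & (y >= self.y0) & (y < self.ymax)
        )

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point (half-open cells)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(np.int64)
        row = np.floor((y - self.y0) / self.cell).astype(np.int64)
        return row, col

    def cell_box(self, row: int, col: int):
        """Square extent of one cell as a shapely box."""
        x = self.x0 + col * self.cell
        y = self.y0 + row * self.cell
        return box(x, y, x + self.cell, y + self.cell)

    def same_grid(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.cell - other.cell) <= tol
            and self.nrows == other.nrows
            and self.ncols == other.ncols
        )


def require_same_grid(a: GridSpec, b: GridSpec) -> None:
    if not a.same_grid(b):
        raise ValueError(f"rasters are not co-registered: {a} vs {b}")
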