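"""Planar raster geometry.

Everything in lurkit lives on a regular planar grid of square cells in
metric coordinates (x increasing right, y increasing up).  Arrays are
row-major with ``values[row, col]``; row 0 is the *southern* edge
(smallest y).  Cell membership uses half-open intervals
``[edge, next_edge)`` so every point inside the grid belongs to exactly
one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridSpec", "FeatureRaster"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster: origin (lower-left corner), cell size
    in meters, and the number of rows/columns."""

    n_rows: int
    n_cols: int
    cell_size: float = 50.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        """Area of one cell in m^2."""
        return self.cell_size ** 2

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.width,
            self.origin_y + self.height,
        )

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of all cell-center coordinates, shape = grid shape."""
        X, Y = np.meshgrid(self.x_centers(), self.y_centers())
        return X, Y

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.bounds
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each coordinate.

        Half-open convention: a point on a shared cell edge belongs to the
        cell on its upper/right side.  Coordinates outside the grid raise
        ``ValueError``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        if not np.all(inside):
            bad = np.argwhere(~np.atleast_1d(inside)).ravel()
            raise ValueError(f"coordinates at positions {bad.tolist()} fall outside the grid")
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def center_of(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (row + 0.5) * self.cell_size
        return x, y


@dataclass
class FeatureRaster:
    """A named single-band raster on a :class:`GridSpec`.

    ``units`` is free-form metadata (e.g. ``"ha"``, ``"index"``, ``"m"``).
    """

    grid: GridSpec
    name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster '{self.name}': values shape {self.values.shape} "
                f"does not match grid shape {self.grid.shape}"
            )

    def with_values(self, values: np.ndarray, name: str | None = None,
                    units: str | None = None) -> "FeatureRaster":
        return FeatureRaster(
            grid=self.grid,
            name=self.name if name is None else name,
            values=values,
            units=self.units if units is None else units,
        )

    def copy(self) -> "FeatureRaster":
        return replace(self, values=self.values.copy())
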