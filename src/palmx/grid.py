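"""Abstract equal-area analysis grid.

All rasters in a run live on one :class:`Grid`: ``n_rows x n_cols`` square
cells of side ``cell_size_km``.  Cell ``(row, col)`` has its center at
``origin + (col, row) * cell_size_km`` (x grows with column index, y with row
index).  Indices are 0-based.  No geographic CRS math happens here; the I/O
layer attaches whatever metadata a GIS needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Equal-area raster grid shared by every layer of one analysis run."""

    n_rows: int
    n_cols: int
    cell_size_km: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates as two ``(n_rows, n_cols)`` arrays."""
        x0, y0 = self.origin
        cols = x0 + np.arange(self.n_cols) * self.cell_size_km
        rows = y0 + np.arange(self.n_rows) * self.cell_size_km
        return np.meshgrid(cols, rows)

    def cell_of_xy(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Round coordinates to the nearest cell index ``(row, col)``."""
        x0, y0 = self.origin
        col = np.rint((np.asarray(x) - x0) / self.cell_size_km).astype(int)
        row = np.rint((np.asarray(y) - y0) / self.cell_size_km).astype(int)
        return row, col

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size_km": self.cell_size_km,
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Grid":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            cell_size_km=float(d["cell_size_km"]),
            origin=tuple(d.get("origin", (0.0, 0.0))),
        )
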