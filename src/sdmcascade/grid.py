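"""Rectangular lat-lon working grid shared by every raster in the pipeline.

Arrays are indexed ``[row, col]`` with row 0 at the *southern* edge, so
``lat = origin_lat + row * cell_size``.  The grid is cell-center registered:
``origin_lon``/``origin_lat`` are the coordinates of the center of cell
``[0, 0]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DomainGrid:
    """A cell-center registered rectangular lat-lon grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; the product must be at least 4.
    cell_size
        Cell edge length in degrees (> 0).
    origin_lon, origin_lat
        Longitude/latitude of the center of the south-western cell.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 0.25
    origin_lon: float = -10.0
    origin_lat: float = 35.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_rows * self.n_cols < 4:
            raise ValueError("grid must contain at least 4 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def lons(self) -> np.ndarray:
        """Cell-center longitudes per column."""
        return self.origin_lon + self.cell_size * np.arange(self.n_cols)

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes per row (south to north)."""
        return self.origin_lat + self.cell_size * np.arange(self.n_rows)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D fields of cell centers."""
        lon, lat = np.meshgrid(self.lons, self.lats)
        return lon, lat

    def fine_shape(self, factor: int) -> tuple[int, int]:
        """Shape of the nested fine grid with ``factor`` sub-cells per edge."""
        if factor < 1:
            raise ValueError("fine factor must be >= 1")
        return (self.n_rows * factor, self.n_cols * factor)


def block_reduce(field: np.ndarray, grid: DomainGrid, func=np.mean) -> np.ndarray:
    """Aggregate a fine-resolution field to the working grid.

    The fine field must nest integrally in the working grid: its shape has to
    be an integer multiple of ``grid.shape`` along both axes.
    """
    field = np.asarray(field, dtype=float)
    nr, nc = grid.shape
    if field.shape == (nr, nc):
        return field.copy()
    if field.shape[0] % nr or field.shape[1] % nc:
        raise ValueError(
            f"fine field of shape {field.shape} does not nest in working grid {grid.shape}"
        )
    fr, fc = field.shape[0] // nr, field.shape[1] // nc
    blocks = field.reshape(nr, fr, nc, fc)
    return func(blocks, axis=(1, 3))
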