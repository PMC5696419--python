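"""Plain-text raster I/O (ESRI ASCII grid).

Every raster artifact of the pipeline is written as a single-band ESRI ASCII
grid (``.asc``), a text format any GIS reads directly.  Internal arrays keep
row 0 at the southern edge; the on-disk format stores rows north-to-south, so
fields are flipped on the way in and out.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid import DomainGrid

NODATA = -9999.0


def write_ascii_grid(path: str | Path, field: np.ndarray, grid: DomainGrid) -> Path:
    """Write a 2-D field aligned to *grid* as an ESRI ASCII raster."""
    field = np.asarray(field, dtype=float)
    if field.shape != grid.shape:
        raise ValueError(f"field shape {field.shape} does not match grid {grid.shape}")
    path = Path(path)
    out = np.where(np.isfinite(field), field, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon - grid.cell_size / 2:.6f}\n"
        f"yllcorner {grid.origin_lat - grid.cell_size / 2:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.flipud(out), fmt="%.6g")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, DomainGrid]:
    """Read an ESRI ASCII raster back into (field, grid)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    grid = DomainGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_lon=header["xllcorner"] + cell / 2,
        origin_lat=header["yllcorner"] + cell / 2,
    )
    field = np.flipud(np.atleast_2d(data))
    nodata = header.get("nodata_value", NODATA)
    field = np.where(field == nodata, np.nan, field)
    return field, grid
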