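"""Elevation grids (digital elevation models) and ESRI ASCII grid I/O.

A reef plot surveyed by photogrammetry is represented here as a regular
raster of substrate heights on square cells -- the 2.5D surface all
terrain metrics consume.  Row 0 of ``heights`` is the northernmost row,
matching the on-disk layout of the ESRI ASCII (.asc) format; the grid
origin is the lower-left *corner* of the raster in a local metric frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "ElevationGrid",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_mask_grid",
]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
_DEFAULT_NODATA = -9999.0


class GridFormatError(ValueError):
    """Raised when an ESRI ASCII grid file cannot be parsed."""


@dataclass
class ElevationGrid:
    """Raster of substrate elevations on square cells.

    Parameters
    ----------
    heights : (rows, cols) float array
        Elevations in metres; row 0 is the northernmost row.
    cell_size : float
        Edge length of a square cell in metres (default 0.01 m, i.e. the
        1 cm resolution typical of fine-scale reef photogrammetry).
    nodata : (rows, cols) bool array, optional
        ``True`` marks missing cells.  Defaults to all-valid.
    origin : (x, y)
        Coordinates of the lower-left corner of the raster.
    bump_ledger : list, optional
        Bookkeeping attached by the synthetic generator: analytic
        descriptions of the coral "bumps" placed on the surface, so that
        degradation can report exact volumes.  Ignored by the metrics.
    """

    heights: np.ndarray
    cell_size: float = 0.01
    nodata: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    bump_ledger: list[Any] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or min(self.heights.shape) < 2:
            raise ValueError("heights must be a 2D array with at least 2 rows and 2 cols")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.nodata is None:
            self.nodata = np.zeros(self.heights.shape, dtype=bool)
        else:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.heights.shape:
                raise ValueError("nodata mask shape must match heights")
        if not np.all(np.isfinite(self.heights[~self.nodata])):
            raise ValueError("non-masked heights must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where a cell holds a real elevation."""
        return ~self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, each shaped like ``heights``."""
        rows, cols = self.shape
        x0, y0 = self.origin
        x = x0 + (np.arange(cols) + 0.5) * self.cell_size
        # row 0 is the top (north) row
        y = y0 + (rows - 0.5 - np.arange(rows)) * self.cell_size
        return np.meshgrid(x, y)


def read_ascii_grid(path: str | Path) -> ElevationGrid:
    """Read an ESRI ASCII grid (.asc) file.

    The header must contain ncols, nrows, xllcorner, yllcorner and
    cellsize (case-insensitive, any order); NODATA_value is optional.
    Cells equal to the NODATA value are masked.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"{path}: line {i + 1}: bad header value {parts[1]!r}") from exc
        else:
            break
    else:
        i += 1
    for key in _HEADER_KEYS:
        if key not in header:
            raise GridFormatError(f"{path}: header missing required field '{key}'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata_value = header.get("nodata_value")

    rows: list[np.ndarray] = []
    for j, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        try:
            row = np.array([float(v) for v in line.split()])
        except ValueError as exc:
            raise GridFormatError(f"{path}: line {j}: non-numeric cell value") from exc
        if row.size != ncols:
            raise GridFormatError(
                f"{path}: line {j}: expected {ncols} values, found {row.size}"
            )
        rows.append(row)
    if len(rows) != nrows:
        raise GridFormatError(f"{path}: expected {nrows} data rows, found {len(rows)}")
    heights = np.vstack(rows)
    mask = np.zeros(heights.shape, dtype=bool)
    if nodata_value is not None:
        mask = heights == nodata_value
        heights = np.where(mask, np.nan, heights)
        heights[mask] = 0.0
    return ElevationGrid(
        heights=heights,
        cell_size=header["cellsize"],
        nodata=mask,
        origin=(header["xllcorner"], header["yllcorner"]),
    )


def write_ascii_grid(
    grid: ElevationGrid, path: str | Path, nodata_value: float = _DEFAULT_NODATA
) -> None:
    """Write an :class:`ElevationGrid` as an ESRI ASCII grid file."""
    rows, cols = grid.shape
    vals = np.where(grid.nodata, nodata_value, grid.heights)
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.10g}\n")
        fh.write(f"yllcorner {grid.origin[1]:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata_value:.10g}\n")
        for r in range(rows):
            fh.write(" ".join(f"{v:.10g}" for v in vals[r]) + "\n")


def read_mask_grid(path: str | Path, grid: ElevationGrid) -> np.ndarray:
    """Read a plot mask stored as a 0/1 .asc grid aligned with ``grid``."""
    mgrid = read_ascii_grid(path)
    if mgrid.shape != grid.shape:
        raise GridFormatError(
            f"mask shape {mgrid.shape} does not match grid shape {grid.shape}"
        )
    mask = (mgrid.heights != 0) & mgrid.valid
    if not mask.any():
        raise GridFormatError("plot mask selects no cells")
    return mask
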