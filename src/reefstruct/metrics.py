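"""Structural-complexity metrics on elevation grids.

Three terrain metrics commonly used to quantify reef habitat structure:

* **surface rugosity** -- ratio of true 3D surface area to planimetric
  (2D) area; 1 for a flat surface, larger for convoluted substrate.
* **vector ruggedness measure (VRM)** -- dispersion of unit vectors
  orthogonal to the surface within a moving window; 0 on any plane,
  approaching 1 for maximally disordered terrain.  Unlike slope-based
  measures it separates ruggedness from steepness.
* **curvature** -- the second derivative of the surface on a 3x3
  neighbourhood (ESRI general curvature, units 1/(100 z-units));
  summarised as the mean of absolute values because both convexities
  and concavities indicate structure.

Boundary and nodata policy: every metric that needs a 3x3 window is
undefined (masked) wherever the window is incomplete, and plot means
exclude undefined cells.  No padding is invented at edges.

The 3D area is computed on the quad mesh of adjacent cell centres,
each quad split into two triangles along its NW-SE diagonal; only
quads whose four corners are selected and non-nodata contribute, and
the planimetric area is accumulated over the same quads so the ratio
is internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .grids import ElevationGrid

__all__ = [
    "PlotComplexity",
    "DegeneratePlotError",
    "surface_area_3d",
    "surface_rugosity",
    "slope_aspect",
    "vrm",
    "curvature",
    "summarize_plot",
]


class DegeneratePlotError(ValueError):
    """Raised when a plot mask leaves nothing to measure."""


@dataclass(frozen=True)
class PlotComplexity:
    """Per-plot structural complexity summary (the row unit of analysis)."""

    surface_rugosity: float   # area_3d / area_2d, dimensionless, >= 1
    terrain_ruggedness: float  # mean VRM in [0, 1]
    mean_abs_curvature: float  # 1/(100 z-units), >= 0
    area_2d: float             # m^2, planimetric
    area_3d: float             # m^2


def _select(grid: ElevationGrid, mask: np.ndarray | None) -> np.ndarray:
    sel = grid.valid if mask is None else (np.asarray(mask, dtype=bool) & grid.valid)
    if mask is not None and np.asarray(mask).shape != grid.shape:
        raise ValueError("mask shape must match grid shape")
    return sel


def surface_area_3d(
    grid: ElevationGrid, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """3D and planimetric surface area (m^2) over the selected plot.

    Returns ``(area_3d, area_2d)`` accumulated over complete quads of
    adjacent cell centres, each quad triangulated along its NW-SE
    diagonal.  Raises :class:`DegeneratePlotError` when no quad has all
    four corners selected and valid.
    """
    sel = _select(grid, mask)
    z = grid.heights
    L = grid.cell_size
    # corner selection per quad: NW, NE, SW, SE in array terms
    q = sel[:-1, :-1] & sel[:-1, 1:] & sel[1:, :-1] & sel[1:, 1:]
    if not q.any():
        raise DegeneratePlotError("degenerate plot: no complete quad of valid cells")
    z_nw = z[:-1, :-1][q]
    z_ne = z[:-1, 1:][q]
    z_sw = z[1:, :-1][q]
    z_se = z[1:, 1:][q]

    def tri_area(dz1_x, dz1_y, dz1, dz2_x, dz2_y, dz2):
        # area of triangle spanned by edge vectors (dz*_x, dz*_y, dz*)
        cx = dz1_y * dz2 - dz1 * dz2_y
        cy = dz1 * dz2_x - dz1_x * dz2
        cz = dz1_x * dz2_y - dz1_y * dz2_x
        return 0.5 * np.sqrt(cx * cx + cy * cy + cz * cz)

    # triangle 1: NW -> NE -> SE; triangle 2: NW -> SE -> SW
    a1 = tri_area(L, 0.0, z_ne - z_nw, L, -L, z_se - z_nw)
    a2 = tri_area(L, -L, z_se - z_nw, 0.0, -L, z_sw - z_nw)
    area_3d = float(np.sum(a1) + np.sum(a2))
    area_2d = float(q.sum() * L * L)
    return area_3d, area_2d


def surface_rugosity(grid: ElevationGrid, mask: np.ndarray | None = None) -> float:
    """Ratio of 3D to 2D surface area over the plot (>= 1)."""
    a3, a2 = surface_area_3d(grid, mask)
    return a3 / a2


def slope_aspect(grid: ElevationGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell slope and aspect by Horn's 3x3 finite differences.

    Returns ``(slope, aspect, valid)``.  Slope is in radians; aspect is
    the downslope direction measured clockwise from north, in radians,
    with flat cells assigned aspect 0.  ``valid`` marks cells whose full
    3x3 neighbourhood exists and is free of nodata; elsewhere the
    outputs are NaN.
    """
    z = grid.heights
    L = grid.cell_size
    rows, cols = z.shape
    ok = grid.valid
    slope = np.full((rows, cols), np.nan)
    aspect = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)
    if rows < 3 or cols < 3:
        return slope, aspect, valid

    # 3x3 neighbourhood, rows north->south:  a b c / d e f / g h i
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i_ = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    win_ok = np.ones(a.shape, dtype=bool)
    for dr in range(3):
        for dc in range(3):
            win_ok &= ok[dr : dr + rows - 2, dc : dc + cols - 2]

    dzdx = ((c + 2 * f + i_) - (a + 2 * d + g)) / (8 * L)          # toward east
    dzdy_s = ((g + 2 * h + i_) - (a + 2 * b + c)) / (8 * L)        # toward south
    sl = np.arctan(np.hypot(dzdx, dzdy_s))
    # downslope unit direction in (east, north) components is -(grad);
    # the north derivative is -dzdy_s
    asp = np.mod(np.arctan2(-dzdx, dzdy_s), 2 * np.pi)
    asp = np.where(sl == 0, 0.0, asp)

    slope[1:-1, 1:-1] = np.where(win_ok, sl, np.nan)
    aspect[1:-1, 1:-1] = np.where(win_ok, asp, np.nan)
    valid[1:-1, 1:-1] = win_ok
    return slope, aspect, valid


def vrm(
    grid: ElevationGrid, mask: np.ndarray | None = None, window: int = 3
) -> tuple[np.ndarray, float]:
    """Vector ruggedness measure per cell and its plot mean.

    Each cell's unit surface normal is decomposed into x, y, z
    components; within a ``window`` x ``window`` neighbourhood the
    resultant vector magnitude \\|R\\| is computed and ruggedness is
    ``1 - |R|/n`` with ``n = window**2``.  Cells whose window contains
    any cell without a defined normal are masked (NaN).  The plot value
    is the mean over mask-selected cells with complete windows.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    rows, cols = grid.shape
    if window > rows or window > cols:
        raise ValueError("window larger than grid")
    sel = _select(grid, mask)
    slope, aspect, nvalid = slope_aspect(grid)

    nz = np.where(nvalid, np.cos(slope), 0.0)
    sxy = np.where(nvalid, np.sin(slope), 0.0)
    nx = sxy * np.where(nvalid, np.sin(aspect), 0.0)
    ny = sxy * np.where(nvalid, np.cos(aspect), 0.0)

    def wsum(arr: np.ndarray) -> np.ndarray:
        return sliding_window_view(arr, (window, window)).sum(axis=(2, 3))

    n = window * window
    sx, sy, sz = wsum(nx), wsum(ny), wsum(nz)
    cnt = wsum(nvalid.astype(float))
    complete = cnt > n - 0.5
    resultant = np.sqrt(sx * sx + sy * sy + sz * sz)
    core = np.where(complete, 1.0 - resultant / n, np.nan)

    half = window // 2
    out = np.full((rows, cols), np.nan)
    out[half:rows - half, half:cols - half] = core
    ok = np.zeros((rows, cols), dtype=bool)
    ok[half:rows - half, half:cols - half] = complete
    use = ok & sel
    if not use.any():
        raise DegeneratePlotError("degenerate plot: no cell with a complete VRM window")
    # dispersion can dip below zero by floating rounding on perfect planes
    out = np.clip(out, 0.0, 1.0)
    return out, float(np.mean(out[use]))


def curvature(
    grid: ElevationGrid, mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """ESRI general curvature per cell and plot mean of absolute values.

    With focal cell Z5, west/east neighbours Z4/Z6, north/south Z2/Z8
    and cell size L:  D = ((Z4+Z6)/2 - Z5)/L^2, E = ((Z2+Z8)/2 - Z5)/L^2,
    curvature = -2(D+E)*100.  Units 1/(100 z-units); positive for
    upwardly convex cells under this sign convention.  Cells with an
    incomplete 3x3 neighbourhood are masked.
    """
    sel = _select(grid, mask)
    z = grid.heights
    L = grid.cell_size
    rows, cols = z.shape
    out = np.full((rows, cols), np.nan)
    ok_cells = np.zeros((rows, cols), dtype=bool)
    if rows >= 3 and cols >= 3:
        ok = grid.valid
        win_ok = np.ones((rows - 2, cols - 2), dtype=bool)
        for dr in range(3):
            for dc in range(3):
                win_ok &= ok[dr : dr + rows - 2, dc : dc + cols - 2]
        z5 = z[1:-1, 1:-1]
        z4, z6 = z[1:-1, :-2], z[1:-1, 2:]
        z2, z8 = z[:-2, 1:-1], z[2:, 1:-1]
        D = ((z4 + z6) / 2 - z5) / (L * L)
        E = ((z2 + z8) / 2 - z5) / (L * L)
        out[1:-1, 1:-1] = np.where(win_ok, -2 * (D + E) * 100, np.nan)
        ok_cells[1:-1, 1:-1] = win_ok
    use = ok_cells & sel
    if not use.any():
        raise DegeneratePlotError("degenerate plot: no cell with a complete 3x3 window")
    return out, float(np.mean(np.abs(out[use])))


def summarize_plot(grid: ElevationGrid, mask: np.ndarray | None = None) -> PlotComplexity:
    """Bundle the three complexity metrics for one plot."""
    a3, a2 = surface_area_3d(grid, mask)
    _, mean_vrm = vrm(grid, mask)
    _, mean_abs_curv = curvature(grid, mask)
    return PlotComplexity(
        surface_rugosity=a3 / a2,
        terrain_ruggedness=mean_vrm,
        mean_abs_curvature=mean_abs_curv,
        area_2d=a2,
        area_3d=a3,
    )
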