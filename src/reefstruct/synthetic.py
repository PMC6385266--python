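"""Synthetic reef surveys with known ground truth.

Real inputs to this pipeline come from Structure-from-Motion
photogrammetry of permanent reef plots.  This module generates
stand-ins whose true properties are known in closed form, so every
downstream stage can be checked end to end:

* parametric surfaces (plane, sinusoid, spherical-cap "coral bump"
  fields) whose rugosity/ruggedness/curvature are analytic or cheaply
  oracle-computable;
* degraded "after" surfaces with an exactly known eroded volume
  (bumps are additive spherical caps, so removal subtracts an analytic
  cap volume);
* before/after point-cloud pairs with a prescribed similarity
  misalignment and labelled corner-pin correspondences, mirroring the
  permanent pins used to co-register repeat surveys;
* plot-record tables drawn from the assumed mixed-model structure
  (random site intercept, period-specific residual variance).

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .clouds import CorrespondencePairs, PointCloud3D, SimilarityTransform
from .grids import ElevationGrid
from .lmm import TERMS, ModelSpec, design_matrix, rescale_half_sd

__all__ = [
    "Bump",
    "SurfaceSpec",
    "DegradationSpec",
    "LMMSimSpec",
    "gen_surface",
    "degrade_surface",
    "grid_to_cloud",
    "simulate_plot_records",
    "compute_density",
    "cap_volume",
]


@dataclass(frozen=True)
class Bump:
    """A spherical-cap bump added onto the base surface.

    ``sphere_radius`` is the radius R of the generating sphere and
    ``height`` the cap height h; the cap's footprint radius is
    sqrt(h(2R - h)) and its volume pi h^2 (3R - h) / 3.
    """

    x: float
    y: float
    sphere_radius: float
    height: float

    @property
    def base_radius(self) -> float:
        return math.sqrt(self.height * (2 * self.sphere_radius - self.height))

    @property
    def volume(self) -> float:
        return math.pi * self.height**2 * (3 * self.sphere_radius - self.height) / 3.0


def cap_volume(sphere_radius: float, height: float) -> float:
    """Volume of a spherical cap, pi h^2 (3R - h) / 3."""
    return math.pi * height**2 * (3 * sphere_radius - height) / 3.0


@dataclass
class SurfaceSpec:
    """Parameters of a synthetic reef surface.

    ``kind`` is one of 'plane', 'sinusoid', 'bumps', 'composite'.
    ``extent`` is the (x, y) footprint in metres and ``cell_size`` the
    raster resolution (default 1 cm, the standard fine-scale reef DEM
    resolution).  Sinusoid: z = amplitude * sin(2 pi x / wavelength).
    Bumps: ``n_bumps`` spherical caps with radii/heights drawn uniformly
    from the given ranges, placed by Poisson-disc (dart-throwing)
    sampling; 'composite' adds tilt + sinusoid + bumps.
    """

    kind: str = "bumps"
    extent: tuple[float, float] = (4.0, 4.0)
    cell_size: float = 0.01
    tilt: float = 0.0                     # radians, applied along x
    amplitude: float = 0.1                # m, sinusoid
    wavelength: float = 0.5               # m, sinusoid
    n_bumps: int = 25
    bump_radius: tuple[float, float] = (0.08, 0.25)   # sphere radii, m
    bump_height_frac: tuple[float, float] = (0.5, 1.0)  # height as fraction of R
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("plane", "sinusoid", "bumps", "composite"):
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if min(self.extent) <= 0 or self.cell_size <= 0:
            raise ValueError("extent and cell_size must be positive")
        if self.kind in ("bumps", "composite") and self.bump_radius[1] >= min(self.extent) / 2:
            raise ValueError("bump radius must be smaller than half the extent")


def _bump_field(
    shape: tuple[int, int], xc: np.ndarray, yc: np.ndarray, bumps: list[Bump]
) -> np.ndarray:
    z = np.zeros(shape)
    for b in bumps:
        d2 = (xc - b.x) ** 2 + (yc - b.y) ** 2
        a2 = b.base_radius**2
        inside = d2 < a2
        if inside.any():
            z[inside] += np.sqrt(b.sphere_radius**2 - d2[inside]) - (
                b.sphere_radius - b.height
            )
    return z


def gen_surface(spec: SurfaceSpec) -> ElevationGrid:
    """Generate a synthetic reef elevation grid (deterministic per seed).

    Bump placements and sizes are recorded on the returned grid's
    ``bump_ledger`` so that :func:`degrade_surface` can report exact
    eroded volumes.
    """
    rng = np.random.default_rng(spec.seed)
    nx = int(round(spec.extent[0] / spec.cell_size))
    ny = int(round(spec.extent[1] / spec.cell_size))
    x = (np.arange(nx) + 0.5) * spec.cell_size
    y = (ny - 0.5 - np.arange(ny)) * spec.cell_size  # row 0 = north
    xc, yc = np.meshgrid(x, y)

    z = np.zeros((ny, nx))
    if spec.kind in ("plane", "composite") and spec.tilt != 0.0:
        z += xc * math.tan(spec.tilt)
    if spec.kind == "plane" and spec.tilt == 0.0:
        pass
    if spec.kind in ("sinusoid", "composite"):
        z += spec.amplitude * np.sin(2 * np.pi * xc / spec.wavelength)

    bumps: list[Bump] = []
    if spec.kind in ("bumps", "composite"):
        r_lo, r_hi = spec.bump_radius
        # keep whole bump footprints clear of the plot boundary: repeat
        # surveys are misaligned, so an edge band is surveyed only once
        # and structure there cannot be compared between surveys
        margin = r_hi + 0.05
        positions: list[tuple[float, float]] = []
        attempts = 0
        while len(positions) < spec.n_bumps and attempts < 200 * spec.n_bumps:
            attempts += 1
            px = rng.uniform(margin, spec.extent[0] - margin)
            py = rng.uniform(margin, spec.extent[1] - margin)
            if all((px - qx) ** 2 + (py - qy) ** 2 > (0.8 * r_hi) ** 2
                   for qx, qy in positions):
                positions.append((px, py))
        for px, py in positions:
            R = rng.uniform(r_lo, r_hi)
            h = R * rng.uniform(*spec.bump_height_frac)
            bumps.append(Bump(x=px, y=py, sphere_radius=R, height=h))
        z += _bump_field(z.shape, xc, yc, bumps)

    return ElevationGrid(
        heights=z, cell_size=spec.cell_size, origin=(0.0, 0.0), bump_ledger=bumps
    )


@dataclass
class DegradationSpec:
    """How to erode a generated surface into its "after" state."""

    fraction_bumps_removed: float = 0.5
    smoothing_radius: float = 0.0         # m; Gaussian sigma of local smoothing
    target_volume_loss: float | None = None  # m^3; overrides the fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_bumps_removed <= 1.0:
            raise ValueError("fraction_bumps_removed must be in [0, 1]")


def degrade_surface(
    grid: ElevationGrid, spec: DegradationSpec
) -> tuple[ElevationGrid, float]:
    """Erode a bump surface; return (after grid, true volume change in m^3).

    A seeded subset of the recorded bumps is removed by subtracting
    their analytic cap profiles (restoring the base surface there), so
    the returned volume change, -sum of removed cap volumes, is exact.
    Optional Gaussian smoothing (mass-preserving away from edges) is
    applied within the removed-bump neighbourhoods to emulate erosion
    of sharp rims.
    """
    ledger = grid.bump_ledger or []
    rng = np.random.default_rng(spec.seed)
    if spec.target_volume_loss is not None:
        order = rng.permutation(len(ledger))
        removed: list[Bump] = []
        total = 0.0
        for i in order:
            if total >= abs(spec.target_volume_loss):
                break
            removed.append(ledger[i])
            total += ledger[i].volume
    else:
        n_rm = int(round(spec.fraction_bumps_removed * len(ledger)))
        idx = rng.choice(len(ledger), size=n_rm, replace=False) if n_rm else []
        removed = [ledger[i] for i in idx]

    xc, yc = grid.cell_centers()
    z = grid.heights - _bump_field(grid.shape, xc, yc, removed)

    if spec.smoothing_radius > 0 and removed:
        sigma = spec.smoothing_radius / grid.cell_size
        smoothed = gaussian_filter(z, sigma=sigma, mode="nearest")
        blend = np.zeros(grid.shape)
        for b in removed:
            d2 = (xc - b.x) ** 2 + (yc - b.y) ** 2
            blend = np.maximum(blend, np.exp(-d2 / (2 * (2 * b.base_radius) ** 2)))
        z = blend * smoothed + (1 - blend) * z

    true_change = -sum(b.volume for b in removed)
    kept = [b for b in ledger if b not in removed]
    after = ElevationGrid(
        heights=z, cell_size=grid.cell_size, nodata=grid.nodata.copy(),
        origin=grid.origin, bump_ledger=kept,
    )
    return after, true_change


def grid_to_cloud(
    grid: ElevationGrid,
    density: float = 40000.0,
    jitter_sd: float = 0.0,
    transform: SimilarityTransform | None = None,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[PointCloud3D, CorrespondencePairs]:
    """Sample a survey point cloud from a surface, with corner pins.

    ``density`` is in points/m^2; sampling is stratified by default
    (one point jittered inside each stratum cell), emulating the dense,
    even coverage of photogrammetric clouds.  ``jitter_sd`` adds
    Gaussian vertical noise.  ``transform`` (if given) moves the whole
    cloud -- including its pins -- into a misaligned survey frame.

    Returns the cloud and the four corner-pin correspondences as
    (surface-frame pin, cloud-frame pin) pairs, so
    ``estimate_similarity(pairs)`` recovers the applied transform and
    ``pairs.swapped()`` is the registration-ready direction
    (cloud frame -> surface frame).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    rows, cols = grid.shape
    L = grid.cell_size
    x0, y0 = grid.origin
    # interpolation domain: cell centres
    xs = x0 + (np.arange(cols) + 0.5) * L
    ys = y0 + (rows - 0.5 - np.arange(rows)) * L      # descending (north first)
    interp = RegularGridInterpolator(
        (ys[::-1], xs), grid.heights[::-1], bounds_error=False, fill_value=None
    )
    xmin, xmax = xs[0], xs[-1]
    ymin, ymax = ys[-1], ys[0]

    if stratified:
        s = 1.0 / math.sqrt(density)
        gx = np.arange(xmin, xmax - s / 2, s)
        gy = np.arange(ymin, ymax - s / 2, s)
        gxx, gyy = np.meshgrid(gx, gy)
        px = (gxx + rng.uniform(0, s, gxx.shape)).ravel()
        py = (gyy + rng.uniform(0, s, gyy.shape)).ravel()
    else:
        n = int(round(density * (xmax - xmin) * (ymax - ymin)))
        px = rng.uniform(xmin, xmax, n)
        py = rng.uniform(ymin, ymax, n)
    pz = interp(np.column_stack([py, px]))
    if jitter_sd > 0:
        pz = pz + rng.normal(0.0, jitter_sd, pz.shape)
    pts = np.column_stack([px, py, pz])

    corners = np.array(
        [[xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax]]
    )
    pin_z = interp(corners[:, ::-1])
    pins_surface = np.column_stack([corners, pin_z])

    T = transform if transform is not None else SimilarityTransform()
    cloud = PointCloud3D(points=T.apply(np.vstack([pts, pins_surface])))
    pins_cloud = cloud.points[-4:]
    pairs = CorrespondencePairs(source=pins_surface, reference=pins_cloud)
    return cloud, pairs


@dataclass
class LMMSimSpec:
    """Generating parameters for plot-record tables.

    Defaults mirror the study design this pipeline targets: 9 sites in
    three local-disturbance strata, 3 plots per site, surveyed before
    and after a heat-stress event, with one plot dropped (27 planned,
    26 analysed).  Coefficients are on the analysis scale (densities
    rescaled to mean 0, SD 0.5) and default to a rugosity-like response:
    a strong negative heat effect, declining baseline with disturbance,
    positive branching/massive density effects, and residual variance
    shrinking after the event (delta_after < 1).
    """

    n_sites: int = 9
    plots_per_site: int = 3
    n_plots_dropped: int = 1
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": 2.2,
            "heat": -0.46,
            "dist_medium": -0.35,
            "dist_high": -0.5,
            "branching": 0.25,
            "plating": 0.0,
            "massive": 0.15,
            "heat:dist_medium": 0.0,
            "heat:dist_high": 0.0,
        }
    )
    sigma_site: float = 0.15
    sigma_resid: float = 0.25
    delta_after: float = 0.6
    # per-disturbance-level mean densities (corals/m^2), gamma shape 2
    branching_mean: tuple[float, float, float] = (6.0, 4.0, 2.0)
    plating_mean: tuple[float, float, float] = (1.5, 1.5, 1.5)
    massive_mean: tuple[float, float, float] = (3.0, 2.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        if min(self.sigma_site, self.sigma_resid, self.delta_after) < 0 or (
            self.sigma_resid == 0
        ):
            raise ValueError("variance parameters must be positive")


def simulate_plot_records(spec: LMMSimSpec) -> pd.DataFrame:
    """Draw a plot-record table from the assumed mixed-model structure.

    y = X beta + b_site + eps with b_site ~ N(0, sigma_site^2) and
    eps ~ N(0, sigma_resid^2 * delta_period^2).  Growth-form densities
    are gamma-distributed with disturbance-dependent means and attached
    unrescaled; the linear predictor uses their rescaled versions, as
    the analysis will.  Returns one row per plot x period with columns
    site, plot, period, disturbance, branching, plating, massive,
    response.
    """
    rng = np.random.default_rng(spec.seed)
    levels = ["low", "medium", "high"]
    site_dist = [levels[i * 3 // spec.n_sites] for i in range(spec.n_sites)]

    rows = []
    for s in range(spec.n_sites):
        lvl = site_dist[s]
        li = levels.index(lvl)
        for p in range(spec.plots_per_site):
            shape = 2.0
            branching = rng.gamma(shape, spec.branching_mean[li] / shape)
            plating = rng.gamma(shape, spec.plating_mean[li] / shape)
            massive = rng.gamma(shape, spec.massive_mean[li] / shape)
            for period in ("before", "after"):
                rows.append(
                    {
                        "site": f"site{s + 1:02d}",
                        "plot": f"site{s + 1:02d}_p{p + 1}",
                        "period": period,
                        "disturbance": lvl,
                        "branching": branching,
                        "plating": plating,
                        "massive": massive,
                    }
                )
    df = pd.DataFrame(rows)
    if spec.n_plots_dropped:
        dropped = rng.choice(df["plot"].unique(), size=spec.n_plots_dropped, replace=False)
        df = df[~df["plot"].isin(dropped)].reset_index(drop=True)

    scaled = df.copy()
    for col in ("branching", "plating", "massive"):
        scaled[col] = rescale_half_sd(df[col])
    full = ModelSpec(terms=TERMS, interaction=True)
    X, names = design_matrix(full, scaled)
    beta = np.array([spec.beta.get(nm, 0.0) for nm in names])

    site_codes = pd.Categorical(df["site"]).codes
    b_site = rng.normal(0.0, spec.sigma_site, size=site_codes.max() + 1)
    sd = spec.sigma_resid * np.where(df["period"] == "after", spec.delta_after, 1.0)
    eps = rng.normal(0.0, 1.0, size=len(df)) * sd
    df["response"] = X @ beta + b_site[site_codes] + eps
    return df


def compute_density(count: float, area: float) -> float:
    """Colonies per square metre: abundance divided by plot area."""
    if area <= 0:
        raise ValueError("area must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / area
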