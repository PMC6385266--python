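"""Point-cloud registration and 2.5D volumetric change.

Repeat photogrammetric surveys of the same reef plot yield dense point
clouds in arbitrary frames (and, because photogrammetric scale is only
as good as its control points, at slightly different scales).  The
change-detection workflow is:

1. a rough alignment from hand-picked correspondences (the permanent
   corner pins of a plot) via the closed-form least-squares similarity
   transform (Umeyama/Horn);
2. fine registration by iterative closest point (ICP) extended to
   estimate a global scale factor at every iteration;
3. 2.5D differencing: both clouds are rasterised onto a common
   horizontal grid and the height differences are integrated into net,
   gain and loss volumes.

Volumes are "2.5D": each cell carries one height (the mean z of its
points), so overhangs are not resolved -- a faithful mirror of
DEM-based reef survey practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .grids import ElevationGrid

__all__ = [
    "PointCloud3D",
    "CorrespondencePairs",
    "SimilarityTransform",
    "ICPResult",
    "VolumeChangeResult",
    "CloudFormatError",
    "DegenerateCorrespondenceError",
    "read_cloud",
    "write_cloud",
    "estimate_similarity",
    "apply_transform",
    "icp_scaled",
    "rasterize_heights",
    "volume_change",
]


class CloudFormatError(ValueError):
    """Raised when a point-cloud file cannot be parsed."""


class DegenerateCorrespondenceError(ValueError):
    """Raised when correspondence points do not determine a similarity."""


@dataclass
class PointCloud3D:
    """Unordered 3D points (metres) from one survey of one plot."""

    points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an N x 3 array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("all coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class CorrespondencePairs:
    """Matched (source, reference) coordinate pairs, e.g. plot corner pins."""

    source: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))
        if self.source.shape != self.reference.shape or self.source.shape[1] != 3:
            raise ValueError("source and reference must be matching N x 3 arrays")

    def __len__(self) -> int:
        return self.source.shape[0]

    def swapped(self) -> "CorrespondencePairs":
        """The same pairs with source and reference roles exchanged."""
        return CorrespondencePairs(self.reference.copy(), self.source.copy())


@dataclass
class SimilarityTransform:
    """p -> scale * R @ p + t with R a proper rotation."""

    scale: float = 1.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points, dtype=float) @ self.rotation.T) + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return SimilarityTransform(
            scale=self.scale * other.scale,
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(
            scale=1.0 / self.scale,
            rotation=Rinv,
            translation=-(Rinv @ self.translation) / self.scale,
        )

    @property
    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def to_array(self) -> np.ndarray:
        """Flat array (scale, R row-major, t) of 13 numbers."""
        return np.concatenate(([self.scale], self.rotation.ravel(), self.translation))

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SimilarityTransform":
        arr = np.asarray(arr, dtype=float).ravel()
        if arr.size != 13:
            raise ValueError("expected 13 numbers: scale, 3x3 rotation, translation")
        return cls(scale=arr[0], rotation=arr[1:10].reshape(3, 3), translation=arr[10:13])


# ---------------------------------------------------------------------------
# I/O: whitespace XYZ and PLY (ascii / binary little-endian)

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: Path) -> PointCloud3D:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudFormatError(f"{path}: not a PLY file")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        while True:
            line = fh.readline()
            if not line:
                raise CloudFormatError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    raise CloudFormatError(f"{path}: property before element")
                if tokens[1] == "list":
                    elements[-1][2].append((tokens[-1], "__list__"))
                else:
                    elements[-1][2].append((tokens[2], tokens[1]))  # (name, type)
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudFormatError(f"{path}: unsupported PLY format {fmt!r}")
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise CloudFormatError(f"{path}: PLY file has no vertex element")
        _, count, props = vertex
        names = [p[0] for p in props]
        if any(p[1] == "__list__" for p in props):
            raise CloudFormatError(f"{path}: list properties on vertices unsupported")
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise CloudFormatError(f"{path}: vertex element missing property '{axis}'")
        if elements.index(vertex) != 0:
            raise CloudFormatError(f"{path}: vertex must be the first element")
        if fmt == "ascii":
            data = np.loadtxt(fh, max_rows=count, ndmin=2)
            if data.shape != (count, len(props)):
                raise CloudFormatError(f"{path}: vertex data shape mismatch")
            cols = {n: data[:, k] for k, (n, _) in enumerate(props)}
        else:
            dtype = np.dtype([(n, "<" + _PLY_DTYPES[t]) for n, t in props])
            raw = np.fromfile(fh, dtype=dtype, count=count)
            if raw.size != count:
                raise CloudFormatError(f"{path}: truncated binary vertex data")
            cols = {n: raw[n].astype(float) for n, _ in props}
        pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    return PointCloud3D(points=pts)


def read_cloud(path: str | Path) -> PointCloud3D:
    """Read a point cloud from .ply (ascii or binary LE) or whitespace XYZ."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return _read_ply(path)
    if path.suffix.lower() in (".xyz", ".txt", ".csv", ".pts"):
        try:
            delimiter = "," if path.suffix.lower() == ".csv" else None
            data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        except ValueError as exc:
            raise CloudFormatError(f"{path}: could not parse XYZ data") from exc
        if data.size == 0:
            raise CloudFormatError(f"{path}: empty point file")
        if data.shape[1] < 3:
            raise CloudFormatError(f"{path}: need at least 3 columns (x y z)")
        return PointCloud3D(points=data[:, :3])
    raise CloudFormatError(f"{path}: unknown point-cloud extension {path.suffix!r}")


def write_cloud(cloud: PointCloud3D, path: str | Path) -> None:
    """Write a point cloud as ascii PLY (.ply) or whitespace XYZ."""
    path = Path(path)
    pts = cloud.points
    if path.suffix.lower() == ".ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(pts)}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write("end_header\n")
            for p in pts:
                fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
    else:
        np.savetxt(path, pts, fmt="%.10g")


# ---------------------------------------------------------------------------
# Registration

def estimate_similarity(pairs: CorrespondencePairs) -> SimilarityTransform:
    """Closed-form least-squares similarity transform (Umeyama).

    Minimises sum ||s R p_i + t - q_i||^2 over scale s > 0, rotation R
    and translation t; exact (to machine precision) when the pairs are
    related by a true similarity.  Requires >= 3 pairs whose source
    points are not collinear.
    """
    if len(pairs) < 3:
        raise DegenerateCorrespondenceError("need at least 3 correspondence pairs")
    P, Q = pairs.source, pairs.reference
    mu_p, mu_q = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - mu_p, Q - mu_q
    var_p = np.mean(np.sum(Pc**2, axis=1))
    if var_p <= 0 or np.linalg.matrix_rank(Pc, tol=1e-10 * max(1.0, np.abs(Pc).max())) < 2:
        raise DegenerateCorrespondenceError(
            "degenerate correspondence: source points collinear or coincident"
        )
    cov = Qc.T @ Pc / len(pairs)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    s = float(np.trace(np.diag(D) @ S) / var_p)
    if not s > 0:
        raise DegenerateCorrespondenceError("degenerate correspondence: non-positive scale")
    t = mu_q - s * R @ mu_p
    return SimilarityTransform(scale=s, rotation=R, translation=t)


def apply_transform(cloud: PointCloud3D, transform: SimilarityTransform) -> PointCloud3D:
    """Return a new cloud with ``transform`` applied to every point."""
    return PointCloud3D(points=transform.apply(cloud.points), labels=cloud.labels)


@dataclass
class ICPResult:
    transform: SimilarityTransform
    rms_history: list[float]
    converged: bool
    n_iter: int


def icp_scaled(
    source: PointCloud3D,
    reference: PointCloud3D,
    init: SimilarityTransform | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    trim_fraction: float = 0.0,
) -> ICPResult:
    """Scale-adjusted iterative closest point registration.

    Alternates (1) nearest-reference-neighbour correspondence for every
    transformed source point with (2) the closed-form similarity fit on
    those correspondences, until the RMS nearest-neighbour residual
    improves by less than ``tol`` metres or ``max_iter`` is reached.
    The returned RMS history is non-increasing (with the default
    ``trim_fraction = 0``, each step is the exact minimiser for its
    correspondence set).

    ``trim_fraction`` optionally discards that fraction of the worst
    correspondences before the fit (robustness to partial overlap).
    """
    if len(source) < 4 or len(reference) < 4:
        raise ValueError("both clouds need at least 4 points for registration")
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must be in [0, 1)")
    T = init if init is not None else SimilarityTransform()
    tree = cKDTree(reference.points)
    src = source.points

    moved = T.apply(src)
    dist, idx = tree.query(moved)
    rms = float(np.sqrt(np.mean(dist**2)))
    history = [rms]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        keep = slice(None)
        if trim_fraction > 0:
            n_keep = max(4, int(np.ceil(len(src) * (1 - trim_fraction))))
            keep = np.argsort(dist)[:n_keep]
        T = estimate_similarity(CorrespondencePairs(src[keep], reference.points[idx[keep]]))
        moved = T.apply(src)
        dist, idx = tree.query(moved)
        new_rms = float(np.sqrt(np.mean(dist**2)))
        history.append(new_rms)
        if history[-2] - new_rms < tol:
            converged = True
            break
    return ICPResult(transform=T, rms_history=history, converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# 2.5D rasterisation and volume differencing

def rasterize_heights(
    cloud: PointCloud3D,
    cell_size: float,
    extent: tuple[float, float, float, float] | None = None,
    agg: str = "mean",
) -> ElevationGrid:
    """Project a cloud onto a horizontal grid of per-cell heights.

    ``extent`` is (xmin, ymin, xmax, ymax); by default the cloud's
    bounding box.  Each cell's height is the mean (or median) z of the
    points falling in it; empty cells are marked nodata, never
    interpolated.
    """
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    pts = cloud.points
    if extent is None:
        xmin, ymin = pts[:, 0].min(), pts[:, 1].min()
        xmax, ymax = pts[:, 0].max(), pts[:, 1].max()
    else:
        xmin, ymin, xmax, ymax = extent
    ncols = max(int(np.ceil((xmax - xmin) / cell_size)), 1)
    nrows = max(int(np.ceil((ymax - ymin) / cell_size)), 1)
    inside = (
        (pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
        & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax)
    )
    ix = np.floor((pts[inside, 0] - xmin) / cell_size).astype(int)
    iy = np.floor((pts[inside, 1] - ymin) / cell_size).astype(int)
    # points exactly on the max edge belong to the last cell
    ix = np.clip(ix, 0, ncols - 1)
    iy = np.clip(iy, 0, nrows - 1)
    zs = pts[inside, 2]
    if zs.size == 0:
        raise ValueError("no points fall inside the requested extent")
    flat = iy * ncols + ix
    counts = np.bincount(flat, minlength=nrows * ncols)
    if agg == "mean":
        sums = np.bincount(flat, weights=zs, minlength=nrows * ncols)
        with np.errstate(invalid="ignore"):
            h = sums / counts
    elif agg == "median":
        h = np.full(nrows * ncols, np.nan)
        order = np.argsort(flat, kind="stable")
        bounds = np.searchsorted(flat[order], np.arange(nrows * ncols + 1))
        for cell in np.nonzero(counts)[0]:
            h[cell] = np.median(zs[order[bounds[cell] : bounds[cell + 1]]])
    else:
        raise ValueError(f"unknown aggregator {agg!r}")
    h = h.reshape(nrows, ncols)
    nodata = counts.reshape(nrows, ncols) == 0
    h = np.where(nodata, 0.0, h)
    # ElevationGrid stores row 0 as the northernmost row
    return ElevationGrid(
        heights=h[::-1].copy(),
        cell_size=cell_size,
        nodata=nodata[::-1].copy(),
        origin=(float(xmin), float(ymin)),
    )


@dataclass
class VolumeChangeResult:
    """Signed 2.5D volume change between two surveys of one plot."""

    height_diff: ElevationGrid     # (after - before) heights, metres
    net_volume: float              # m^3, signed
    gain_volume: float             # m^3, >= 0
    loss_volume: float             # m^3, <= 0
    n_compared_cells: int
    n_excluded_cells: int


def volume_change(
    before: PointCloud3D,
    after: PointCloud3D,
    cell_size: float = 0.01,
    agg: str = "mean",
) -> VolumeChangeResult:
    """2.5D volumetric change between two registered clouds.

    Both clouds are rasterised on a common horizontal grid (union of
    bounding boxes); per compared cell dh = h_after - h_before; net
    volume is sum(dh) * cell^2 with gains and losses accumulated
    separately.  Cells undefined in either raster are excluded and
    counted.  ``after`` must already be registered into ``before``'s
    frame.
    """
    lo = np.minimum(before.points.min(axis=0), after.points.min(axis=0))
    hi = np.maximum(before.points.max(axis=0), after.points.max(axis=0))
    extent = (float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1]))
    gb = rasterize_heights(before, cell_size, extent, agg=agg)
    ga = rasterize_heights(after, cell_size, extent, agg=agg)
    both = gb.valid & ga.valid
    n_cmp = int(both.sum())
    if n_cmp == 0:
        raise ValueError("no comparable area: zero overlapping defined cells")
    dh = np.where(both, ga.heights - gb.heights, 0.0)
    cell_area = cell_size * cell_size
    net = float(dh.sum() * cell_area)
    gain = float(dh[dh > 0].sum() * cell_area)
    loss = float(dh[dh < 0].sum() * cell_area)
    diff = ElevationGrid(
        heights=np.where(both, dh, 0.0),
        cell_size=cell_size,
        nodata=~both,
        origin=gb.origin,
    )
    return VolumeChangeResult(
        height_diff=diff,
        net_volume=net,
        gain_volume=gain,
        loss_volume=loss,
        n_compared_cells=n_cmp,
        n_excluded_cells=int((~both).sum()),
    )
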