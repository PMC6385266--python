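import numpy as np
import pytest

from reefstruct import ElevationGrid


@pytest.fixture
def flat_grid():
    """20x20 horizontal plane at z = 0, 1 cm cells."""
    return ElevationGrid(np.zeros((20, 20)), cell_size=0.01)


@pytest.fixture
def plane45_grid():
    """Plane inclined at 45 degrees along x, 1 cm cells."""
    x = (np.arange(20) + 0.5) * 0.01
    return ElevationGrid(np.tile(x, (20, 1)), cell_size=0.01)


@pytest.fixture
def rough_grid():
    """Seeded random rough surface for oracle-equivalence checks."""
    rng = np.random.default_rng(42)
    return ElevationGrid(rng.normal(0.0, 0.02, (30, 30)), cell_size=0.01)


def naive_vrm(grid: ElevationGrid, window: int = 3) -> np.ndarray:
    """Double-loop VRM oracle: independent of the vectorised implementation."""
    from reefstruct import slope_aspect

    slope, aspect, valid = slope_aspect(grid)
    rows, cols = grid.shape
    half = window // 2
    out = np.full((rows, cols), np.nan)
    for r in range(half, rows - half):
        for c in range(half, cols - half):
            sx = sy = sz = 0.0
            complete = True
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    if not valid[r + dr, c + dc]:
                        complete = False
                        break
                    s, a = slope[r + dr, c + dc], aspect[r + dr, c + dc]
                    sx += np.sin(s) * np.sin(a)
                    sy += np.sin(s) * np.cos(a)
                    sz += np.cos(s)
                if not complete:
                    break
            if complete:
                n = window * window
                out[r, c] = 1.0 - np.sqrt(sx**2 + sy**2 + sz**2) / n
    return out


def naive_curvature(grid: ElevationGrid) -> np.ndarray:
    """Double-loop ESRI curvature oracle."""
    z = grid.heights
    L = grid.cell_size
    rows, cols = grid.shape
    ok = grid.valid
    out = np.full((rows, cols), np.nan)
    for r in range(1, rows - 1):
        for c in range(1, cols - 1):
            if not ok[r - 1 : r + 2, c - 1 : c + 2].all():
                continue
            D = ((z[r, c - 1] + z[r, c + 1]) / 2 - z[r, c]) / L**2
            E = ((z[r - 1, c] + z[r + 1, c]) / 2 - z[r, c]) / L**2
            out[r, c] = -2 * (D + E) * 100
    return out


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
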