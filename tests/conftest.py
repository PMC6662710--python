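"""Shared fixtures and brute-force oracles.

The oracles here deliberately re-derive results by direct enumeration
(per-voxel set operations, explicit structuring-element loops) so they stay
independent of the vectorized implementations they check.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mandisym import VoxelMask

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_mask(rng, shape, p=0.3, spacing=1.0, origin=(0.0, 0.0, 0.0)) -> VoxelMask:
    return VoxelMask(rng.random(shape) < p, spacing, np.asarray(origin, float))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def ball_offsets(radius: int) -> list[tuple[int, int, int]]:
    """All integer offsets v with |v| <= radius (Euclidean)."""
    r = int(radius)
    out = []
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                if dx * dx + dy * dy + dz * dz <= r * r:
                    out.append((dx, dy, dz))
    return out


def brute_dilate(data: np.ndarray, radius: int) -> np.ndarray:
    """Set dilation by the Euclidean ball, computed voxel by voxel."""
    out = np.zeros_like(data)
    nx, ny, nz = data.shape
    offsets = ball_offsets(radius)
    for i, j, k in zip(*np.nonzero(data)):
        for dx, dy, dz in offsets:
            x, y, z = i + dx, j + dy, k + dz
            if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                out[x, y, z] = True
    return out


def brute_erode(data: np.ndarray, radius: int) -> np.ndarray:
    """Set erosion: keep a voxel iff the whole ball around it is foreground
    (balls reaching outside the grid fail, i.e. the border is background)."""
    out = np.zeros_like(data)
    nx, ny, nz = data.shape
    offsets = ball_offsets(radius)
    for i, j, k in zip(*np.nonzero(data)):
        ok = True
        for dx, dy, dz in offsets:
            x, y, z = i + dx, j + dy, k + dz
            if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz) or not data[x, y, z]:
                ok = False
                break
        out[i, j, k] = ok
    return out


def brute_close(data: np.ndarray, radius: int) -> np.ndarray:
    """Closing with background padding so edges behave like open space."""
    r = int(radius)
    padded = np.pad(data, r)
    closed = brute_erode(brute_dilate(padded, r), r)
    return closed[r:-r, r:-r, r:-r]


def brute_overlap_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, int]:
    """(|A|, |B|, |A∩B|, |AΔB|) by per-voxel triple counting."""
    ca = cb = ci = cn = 0
    for av, bv in zip(a.ravel(), b.ravel()):
        if av:
            ca += 1
        if bv:
            cb += 1
        if av and bv:
            ci += 1
        if av != bv:
            cn += 1
    return ca, cb, ci, cn


def brute_face_count_area(data: np.ndarray, spacing: float) -> float:
    """Exposed-face count by explicit neighbour loops."""
    nx, ny, nz = data.shape
    faces = 0
    for i, j, k in zip(*np.nonzero(data)):
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            x, y, z = i + dx, j + dy, k + dz
            if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz) or not data[x, y, z]:
                faces += 1
    return faces * spacing**2
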