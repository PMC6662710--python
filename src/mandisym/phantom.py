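"""Synthetic mandible phantoms with known ground-truth asymmetry.

The generator builds a horseshoe-shaped "mandible" — a half-torus body arc
plus two vertical ramus slabs topped by spherical condylar knobs — inside a
HU volume, together with the cephalometric landmarks placed analytically
from the same parametric construction, so every landmark is exactly
consistent with the voxelized anatomy.  An optional soft-tissue shell
surrounds the bone.  HU values sit strictly inside the standard bone
(320–520) and soft-tissue (−480 to −360) thresholding bands, so noiseless
phantoms binarize exactly back to the generated masks.

Asymmetry is parameterized and applied to the right side only, so the
deviation (Dev) side is known a priori:

* ``lateral_shift_mm`` translates the whole mandible toward the patient's
  right relative to the fixed cranial landmarks (misalignment — moves
  menton off the midsagittal plane);
* ``right_scale`` (per axis) and ``right_yaw_deg`` deform the right ramus
  and condyle about the right gonion (structural asymmetry).

World frame: +x = patient left, +y = anterior, +z = superior.  The facial
midsagittal plane of a phantom is always x = 0, which is a grid mid-plane,
so mirroring across it is an exact index flip.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import LandmarkSet, Plane
from .voxel_ops import HUVolume, VoxelMask

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomGeometryError",
    "CohortSubject",
    "make_mandible_phantom",
    "make_box_pair",
    "box_pair_dice",
    "make_cohort",
    "DEFAULT_COHORT_SPEC",
]


class PhantomGeometryError(ValueError):
    """The requested structures do not fit inside the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic mandible volume.

    Geometric sizes are in mm and chosen to mimic adult mandibular
    proportions at reduced overall scale; HU values sit strictly inside the
    standard binarization bands.
    """

    shape: tuple[int, int, int] = (128, 128, 96)
    spacing: float = 0.78
    body_arc_radius: float = 28.0
    body_tube_radius: float = 7.0
    body_arc_half_angle_deg: float = 112.0
    ramus_height: float = 34.0
    ramus_width: float = 9.0
    ramus_depth: float = 12.0
    condyle_radius: float = 5.5
    body_base_z: float = 16.0
    # asymmetry (applied to the right side; identity = symmetric phantom)
    right_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lateral_shift_mm: float = 0.0
    right_yaw_deg: float = 0.0
    # soft tissue and intensities
    soft_shell_mm: float = 5.0
    hu_bone: float = 400.0
    hu_soft: float = -420.0
    hu_background: float = -1000.0
    hu_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.right_scale):
            raise ValueError("right_scale components must be positive")
        if not 320.0 < self.hu_bone < 520.0:
            raise ValueError("hu_bone must lie strictly inside the bone band (320, 520)")
        if not -480.0 < self.hu_soft < -360.0:
            raise ValueError("hu_soft must lie strictly inside the soft band (-480, -360)")
        if len(self.shape) != 3 or any(int(n) < 8 for n in self.shape):
            raise ValueError("grid shape must be 3D with at least 8 voxels per axis")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.hu_noise_sd < 0:
            raise ValueError("hu_noise_sd must be >= 0")

    @property
    def origin(self) -> np.ndarray:
        """World origin putting x = 0 and y = 0 at grid mid-planes, z from 0."""
        nx, ny, _ = self.shape
        s = self.spacing
        return np.array([-s * (nx - 1) / 2.0, -s * (ny - 1) / 2.0, 0.0])


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth recorded at generation time."""

    dev_side: str  # "right" when lateral_shift_mm > 0, else "midline"
    menton_deviation_mm: float
    lateral_shift_mm: float
    right_scale: tuple[float, float, float]
    right_yaw_deg: float
    ramal_length_left_mm: float
    ramal_length_right_mm: float
    bone_voxel_count: int
    msp: Plane = field(default_factory=lambda: Plane(np.array([1.0, 0.0, 0.0]), 0.0))


def _canonical_landmarks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Landmarks of the symmetric (canonical) construction."""
    R = spec.body_arc_radius
    r = spec.body_tube_radius
    zb = spec.body_base_z
    phi = np.deg2rad(spec.body_arc_half_angle_deg)
    xg, yg = R * np.sin(phi), R * np.cos(phi)
    h = spec.ramus_height
    rc = spec.condyle_radius
    dr = spec.ramus_depth
    w = spec.ramus_width
    lm: dict[str, np.ndarray] = {
        "Me": np.array([0.0, R, zb - r]),
        "Pog": np.array([0.0, R + r, zb]),
        "B_point": np.array([0.0, R + 0.8 * r, zb + 0.6 * r]),
        "G": np.array([0.0, R - r, zb]),
        "N": np.array([0.0, 40.0, 58.0]),
        "S": np.array([0.0, 6.0, 52.0]),
    }
    for side, sx in (("left", 1.0), ("right", -1.0)):
        go_post = np.array([sx * xg, yg - r, zb])
        go_inf = np.array([sx * xg, yg, zb - r])
        lm[f"Go_post_{side}"] = go_post
        lm[f"Go_inf_{side}"] = go_inf
        lm[f"Go_mid_{side}"] = (go_post + go_inf) / 2.0
        lm[f"Con_{side}"] = np.array([sx * xg, yg, zb + h + rc])
        lm[f"J_lat_{side}"] = np.array([sx * (xg + w / 2), yg + dr / 2, zb + 4.0])
        lm[f"J_med_{side}"] = np.array([sx * (xg - w / 2), yg + dr / 2, zb + 4.0])
        lm[f"Or_{side}"] = np.array([sx * 26.0, 30.0, 48.0])
        lm[f"Po_{side}"] = np.array([sx * 38.0, -18.0, 48.0])
    return lm


def _right_transform(spec: PhantomSpec, anchor: np.ndarray):
    """Forward map T (canonical -> deformed) of the right ramus/condyle and
    its inverse, as (matrix, anchor) pairs: T(q) = a + M (q - a)."""
    yaw = np.deg2rad(spec.right_yaw_deg)
    c, s = np.cos(yaw), np.sin(yaw)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    S = np.diag(spec.right_scale)
    M = Rz @ S
    return M, np.linalg.inv(M), anchor


def _bone_masks(spec: PhantomSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Voxelize the phantom bone and return (mask, world landmarks)."""
    nx, ny, nz = spec.shape
    s = spec.spacing
    origin = spec.origin
    X = origin[0] + s * np.arange(nx)[:, None, None]
    Y = origin[1] + s * np.arange(ny)[None, :, None]
    Z = origin[2] + s * np.arange(nz)[None, None, :]

    lm = _canonical_landmarks(spec)
    shift = np.array([spec.lateral_shift_mm, 0.0, 0.0])  # mandible moves to -x
    R = spec.body_arc_radius
    r = spec.body_tube_radius
    zb = spec.body_base_z
    phi_max = np.deg2rad(spec.body_arc_half_angle_deg)
    xg, yg = R * np.sin(phi_max), R * np.cos(phi_max)
    h, rc = spec.ramus_height, spec.condyle_radius
    w, dr = spec.ramus_width, spec.ramus_depth

    # canonical coordinates of each world voxel center (mandible-wide shift)
    Xc = X + shift[0]

    def arc_mask(xq, yq, zq):
        rho = np.sqrt(xq**2 + yq**2)
        ang = np.arctan2(xq, yq)
        return (
            ((rho - R) ** 2 + (zq - zb) ** 2 <= r**2)
            & (np.abs(ang) <= phi_max)
        )

    def ramus_mask(xq, yq, zq, sx):
        slab = (
            (np.abs(xq - sx * xg) <= w / 2)
            & (np.abs(yq - yg) <= dr / 2)
            & (zq >= zb)
            & (zq <= zb + h)
        )
        knob = (xq - sx * xg) ** 2 + (yq - yg) ** 2 + (zq - (zb + h)) ** 2 <= rc**2
        return slab | knob

    bone = arc_mask(Xc, Y, Z)
    bone |= ramus_mask(Xc, Y, Z, +1.0)  # left ramus + condyle, undeformed

    anchor = lm["Go_mid_right"].copy()
    M, Minv, a = _right_transform(spec, anchor)
    identity_right = np.allclose(M, np.eye(3))
    if identity_right:
        bone |= ramus_mask(Xc, Y, Z, -1.0)
    else:
        # membership(p) = canonical(a + Minv (p_c - a)) for the right pieces
        dx, dy, dz = Xc - a[0], Y - a[1], Z - a[2]
        Xq = a[0] + Minv[0, 0] * dx + Minv[0, 1] * dy + Minv[0, 2] * dz
        Yq = a[1] + Minv[1, 0] * dx + Minv[1, 1] * dy + Minv[1, 2] * dz
        Zq = a[2] + Minv[2, 0] * dx + Minv[2, 1] * dy + Minv[2, 2] * dz
        bone |= ramus_mask(Xq, Yq, Zq, -1.0)

    # world-space landmarks
    world: dict[str, np.ndarray] = {}
    right_deformed = (
        "Con_right", "Go_post_right", "Go_mid_right", "Go_inf_right",
        "J_lat_right", "J_med_right",
    )
    cranial = ("N", "S", "Or_left", "Or_right", "Po_left", "Po_right")
    for name, q in lm.items():
        if name in cranial:
            world[name] = q.copy()
        elif name in right_deformed:
            world[name] = a + M @ (q - a) - shift
        else:
            world[name] = q - shift
    return bone, world


def _check_fits(spec: PhantomSpec, world_lm: dict[str, np.ndarray]) -> None:
    nx, ny, nz = spec.shape
    s = spec.spacing
    lo = spec.origin
    hi = lo + s * (np.array([nx, ny, nz]) - 1)
    # the listed landmarks all sit on the bone surface, so the only extra
    # reach beyond them is the soft-tissue shell
    margin = spec.soft_shell_mm + spec.spacing
    for name in ("Con_left", "Con_right", "Me", "Pog",
                 "Go_post_left", "Go_post_right", "Go_inf_left", "Go_inf_right"):
        p = world_lm[name]
        if np.any(p - margin < lo) or np.any(p + margin > hi):
            raise PhantomGeometryError(
                f"structure near landmark {name} at {np.round(p, 1)} exceeds the "
                f"grid bounds [{np.round(lo, 1)}, {np.round(hi, 1)}]"
            )


def make_mandible_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[HUVolume, LandmarkSet, PhantomTruth]:
    """Generate a mandible-like HU volume, its landmarks, and ground truth."""
    spec = spec or PhantomSpec()
    bone, world_lm = _bone_masks(spec)
    _check_fits(spec, world_lm)

    hu = np.full(spec.shape, spec.hu_background, dtype=float)
    if spec.soft_shell_mm > 0:
        dist = ndimage.distance_transform_edt(~bone) * spec.spacing
        soft = (dist <= spec.soft_shell_mm) & ~bone
        hu[soft] = spec.hu_soft
    hu[bone] = spec.hu_bone
    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.hu_noise_sd, size=spec.shape)

    landmarks = LandmarkSet(world_lm)
    dev_side = "right" if spec.lateral_shift_mm > 0 else (
        "left" if spec.lateral_shift_mm < 0 else "midline"
    )
    truth = PhantomTruth(
        dev_side=dev_side,
        menton_deviation_mm=abs(spec.lateral_shift_mm),
        lateral_shift_mm=spec.lateral_shift_mm,
        right_scale=spec.right_scale,
        right_yaw_deg=spec.right_yaw_deg,
        ramal_length_left_mm=float(
            np.linalg.norm(world_lm["Con_left"] - world_lm["Go_mid_left"])
        ),
        ramal_length_right_mm=float(
            np.linalg.norm(world_lm["Con_right"] - world_lm["Go_mid_right"])
        ),
        bone_voxel_count=int(bone.sum()),
    )
    return HUVolume(hu, spec.spacing, spec.origin), landmarks, truth


# ---------------------------------------------------------------------------
# Box-pair phantoms: closed-form oracle for the overlap statistics
# ---------------------------------------------------------------------------

def box_pair_dice(left_dims, right_dims) -> float:
    """Closed-form Dice of two corner-aligned boxes after mirroring:
    2 ∏ min(l_i, r_i) / (∏ l_i + ∏ r_i)."""
    left = np.asarray(left_dims, dtype=float)
    right = np.asarray(right_dims, dtype=float)
    inter = np.prod(np.minimum(left, right))
    return float(2.0 * inter / (np.prod(left) + np.prod(right)))


def make_box_pair(
    left_dims: tuple[int, int, int],
    right_dims: tuple[int, int, int],
    spacing: float = 1.0,
    right_offset: tuple[int, int, int] = (0, 0, 0),
) -> tuple[VoxelMask, VoxelMask, Plane]:
    """Two axis-aligned boxes mirror-placed about a grid mid-plane (x = 0).

    Both boxes touch the mirror plane with one face and share the same
    (y, z) corner, so after reflecting the left box its overlap with the
    right box is ``∏ min(l_i, r_i)`` voxels and the Dice index equals the
    closed form of :func:`box_pair_dice`.  ``right_offset`` (voxels, >= 0)
    pushes the right box away from that aligned position along each axis;
    offsets at least as large as the box extents make the pair disjoint
    after mirroring.

    Returns (left mask, right mask, mirror plane); the masks share one grid.
    """
    left = tuple(int(v) for v in left_dims)
    right = tuple(int(v) for v in right_dims)
    off = tuple(int(v) for v in right_offset)
    if any(v <= 0 for v in left + right):
        raise ValueError("box dimensions must be positive")
    if any(v < 0 for v in off):
        raise ValueError("right_offset components must be >= 0")
    pad = 2
    half_nx = max(left[0], right[0] + off[0]) + pad
    nx = 2 * half_nx
    ny = pad + max(left[1], right[1] + off[1]) + pad
    nz = pad + max(left[2], right[2] + off[2]) + pad
    origin = np.array([-spacing * (nx - 1) / 2.0, 0.0, 0.0])
    grid = np.zeros((nx, ny, nz), dtype=bool)

    left_data = grid.copy()
    left_data[
        half_nx : half_nx + left[0],
        pad : pad + left[1],
        pad : pad + left[2],
    ] = True
    right_data = grid.copy()
    right_data[
        half_nx - off[0] - right[0] : half_nx - off[0],
        pad + off[1] : pad + off[1] + right[1],
        pad + off[2] : pad + off[2] + right[2],
    ] = True

    plane = Plane(np.array([1.0, 0.0, 0.0]), 0.0)
    return (
        VoxelMask(left_data, spacing, origin),
        VoxelMask(right_data, spacing, origin),
        plane,
    )


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

#: Default phantom geometry for cohort work: same anatomy in mm, coarser
#: grid so a 20-subject, two-timepoint cohort pipeline runs in minutes.
DEFAULT_COHORT_SPEC = PhantomSpec(shape=(96, 96, 72), spacing=1.0)


@dataclass(frozen=True)
class CohortSubject:
    """One synthetic subject: phantom specs before (T1) and after (T2)
    surgery.  Volumes are materialized on demand with
    :func:`make_mandible_phantom` to keep cohort memory flat."""

    subject_id: str
    t1_spec: PhantomSpec
    t2_spec: PhantomSpec

    def generate(self, timepoint: str):
        spec = {"T1": self.t1_spec, "T2": self.t2_spec}[timepoint]
        return make_mandible_phantom(spec)


def _scaled_asymmetry(spec: PhantomSpec, factor: float) -> PhantomSpec:
    """Shrink all asymmetry parameters toward identity by ``factor``
    (factor 0 -> perfectly symmetric, 1 -> unchanged)."""
    scale = tuple(1.0 - factor * (1.0 - s) for s in spec.right_scale)
    return dataclasses.replace(
        spec,
        right_scale=scale,
        lateral_shift_mm=factor * spec.lateral_shift_mm,
        right_yaw_deg=factor * spec.right_yaw_deg,
    )


def make_cohort(
    n_subjects: int = 20,
    seed: int = 0,
    reduction: float = 0.5,
    base_spec: PhantomSpec | None = None,
    shift_range_mm: tuple[float, float] = (4.5, 8.0),
    ramus_scale_range: tuple[float, float] = (0.82, 0.94),
    yaw_range_deg: tuple[float, float] = (2.0, 6.0),
) -> list[CohortSubject]:
    """Synthetic surgical cohort: T1 asymmetry drawn per subject, T2
    asymmetry = T1 × ``reduction``.

    Default T1 distributions emulate the clinical inclusion picture: menton
    deviation uniform in 4.5–8 mm (all toward the right, so Dev side is
    right for every subject), right ramus height scale 0.82–0.94 (Dev-side
    ramus shorter), right ramus yaw 2–6°.  ``reduction`` = 0.5 emulates
    surgery halving each asymmetry parameter at T2.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if not 0.0 <= reduction <= 1.0:
        raise ValueError("reduction must be in [0, 1]")
    base = base_spec or DEFAULT_COHORT_SPEC
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        shift = float(rng.uniform(*shift_range_mm))
        sz = float(rng.uniform(*ramus_scale_range))
        yaw = float(rng.uniform(*yaw_range_deg))
        t1 = dataclasses.replace(
            base,
            lateral_shift_mm=shift,
            right_scale=(1.0, 1.0, sz),
            right_yaw_deg=yaw,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        t2 = dataclasses.replace(
            _scaled_asymmetry(t1, reduction),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append(CohortSubject(f"S{i + 1:03d}", t1, t2))
    return subjects
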