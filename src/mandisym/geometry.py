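"""Cephalometric landmarks, reference planes, and rigid transforms.

All geometry lives in world (patient) coordinates measured in millimetres.
The package convention after reorientation is: +x = patient left,
+y = anterior, +z = superior.  Under that convention a positive signed
distance from the midsagittal plane means "on the patient's left".

Reference planes handled here:

* FHP — Frankfort horizontal plane, through both porions and the left
  orbitale; the "horizontal" of the skull.
* MSP — facial midsagittal plane, through nasion and sella, constructed
  perpendicular to the FHP.
* AMP — absolute mandibular midsagittal plane, through menton (Me),
  supramentale (B) and the genial tubercle (G); the mandible's own
  median plane.
* Ramus/body sectioning plane, through gonion midpoint (Go_mid) and the
  lateral/medial junction points (J_lat, J_med) of one hemi-mandible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GeometryError",
    "DegenerateGeometryError",
    "GeometryInconsistencyError",
    "MissingLandmarkError",
    "LandmarkSet",
    "Plane",
    "RigidTransform",
    "CORE_LANDMARK_NAMES",
    "BILATERAL_PAIRS",
    "plane_from_points",
    "plane_through_two_points_perpendicular_to",
    "signed_distance",
    "reflect_point",
    "reorientation_transform",
]

_UNIT_TOL = 1e-9
_CROSS_TOL = 1e-12
_PERP_TOL_RAD = 1e-6


class GeometryError(ValueError):
    """Base class for geometric construction failures."""


class DegenerateGeometryError(GeometryError):
    """Inputs do not determine the requested construction (collinear points,
    direction parallel to a normal, ...)."""


class GeometryInconsistencyError(GeometryError):
    """Inputs violate a geometric consistency requirement (e.g. reference
    planes that should be perpendicular are not)."""


class MissingLandmarkError(KeyError):
    """A computation requested landmarks that are absent from the set."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"non-finite coordinates: {a}")
    return a


# The conventional 14 cephalometric landmarks (bilateral ones counted once),
# expanded to explicit left/right names for the bilateral ones plus the
# midline points.  "B_point" is supramentale (the cephalometric B point).
CORE_LANDMARK_NAMES: tuple[str, ...] = (
    "N", "S",
    "Or_left", "Or_right",
    "Po_left", "Po_right",
    "Con_left", "Con_right",
    "J_lat_left", "J_lat_right",
    "J_med_left", "J_med_right",
    "Go_post_left", "Go_post_right",
    "Go_mid_left", "Go_mid_right",
    "Go_inf_left", "Go_inf_right",
    "Me", "Pog", "B_point", "G",
)

BILATERAL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (n, n.replace("_left", "_right"))
    for n in CORE_LANDMARK_NAMES
    if n.endswith("_left")
)


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3D landmarks in millimetres, world coordinates.

    Landmarks are validated for finiteness on construction.  Completeness is
    checked lazily: each computation calls :meth:`require` with the names it
    needs, so partial sets are usable.  Left/right pairs present in the set
    must be distinct points.
    """

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, p in self.points.items():
            a = _as_point(p)
            a.flags.writeable = False
            clean[str(name)] = a
        object.__setattr__(self, "points", clean)
        for left, right in BILATERAL_PAIRS:
            if left in clean and right in clean:
                if np.array_equal(clean[left], clean[right]):
                    raise GeometryError(
                        f"bilateral landmarks {left!r} and {right!r} coincide"
                    )

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __len__(self) -> int:
        return len(self.points)

    def names(self) -> tuple[str, ...]:
        return tuple(self.points)

    def require(self, names: Iterable[str]) -> None:
        """Raise :class:`MissingLandmarkError` naming every absent landmark."""
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(
                f"missing landmarks: {', '.join(missing)}"
            )

    def transformed(self, transform: "RigidTransform") -> "LandmarkSet":
        return LandmarkSet(
            {n: transform.apply_point(p) for n, p in self.points.items()}
        )

    # ---- file I/O ---------------------------------------------------------

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[float]]) -> "LandmarkSet":
        return cls({n: np.asarray(v, dtype=float) for n, v in mapping.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        with open(path) as fh:
            data = json.load(fh)
        return cls.from_mapping(data)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkSet":
        """CSV with header ``name,x,y,z``."""
        points: dict[str, np.ndarray] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                points[row["name"]] = np.array(
                    [float(row["x"]), float(row["y"]), float(row["z"])]
                )
        return cls(points)

    @classmethod
    def from_file(cls, path: str | Path) -> "LandmarkSet":
        path = Path(path)
        if path.suffix.lower() == ".json":
            return cls.from_json(path)
        if path.suffix.lower() in (".csv", ".tsv", ".txt"):
            return cls.from_csv(path)
        raise ValueError(f"unrecognised landmark file type: {path}")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({n: list(p) for n, p in self.points.items()}, fh, indent=1)


@dataclass(frozen=True)
class Plane:
    """Oriented infinite plane { p : n·p = d } with |n| = 1, d in mm."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = _as_point(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > 1e-6:
            raise GeometryError(f"plane normal not unit length: |n|={np.linalg.norm(n)}")
        n = n / np.linalg.norm(n)  # tighten to 1e-9
        n.flags.writeable = False
        object.__setattr__(self, "normal", n)
        d = float(self.offset)
        if not np.isfinite(d):
            raise GeometryError("plane offset must be finite")
        object.__setattr__(self, "offset", d)

    @classmethod
    def from_normal_point(cls, normal, point) -> "Plane":
        n = _as_point(normal)
        norm = np.linalg.norm(n)
        if norm < _CROSS_TOL:
            raise DegenerateGeometryError("zero-length plane normal")
        n = n / norm
        return cls(n, float(n @ _as_point(point)))

    def flipped(self) -> "Plane":
        """Same plane, opposite orientation."""
        return Plane(-self.normal, -self.offset)

    def oriented_toward(self, point) -> "Plane":
        """Return this plane oriented so *point* has non-negative distance."""
        if signed_distance(point, self) < 0:
            return self.flipped()
        return self


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points.

    Normal direction is fixed by the cross product (p2-p1) x (p3-p1).
    """
    a, b, c = _as_point(p1), _as_point(p2), _as_point(p3)
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n)
    if norm < _CROSS_TOL:
        raise DegenerateGeometryError(
            "points are collinear or coincident; no unique plane"
        )
    n = n / norm
    return Plane(n, float(n @ a))


def plane_through_two_points_perpendicular_to(p1, p2, ref: Plane) -> Plane:
    """Plane containing ``p1`` and ``p2`` and perpendicular to ``ref``.

    This is the construction of the facial midsagittal plane: through nasion
    and sella, perpendicular to the Frankfort horizontal plane.  The normal is
    ``normalize((p2 - p1) x n_ref)``.
    """
    a, b = _as_point(p1), _as_point(p2)
    n = np.cross(b - a, ref.normal)
    norm = np.linalg.norm(n)
    if norm < _CROSS_TOL:
        raise DegenerateGeometryError(
            "direction between points is parallel to the reference normal "
            "(or points coincide); plane underdetermined"
        )
    n = n / norm
    return Plane(n, float(n @ a))


def signed_distance(p, plane: Plane) -> float:
    """Signed distance n·p - d from *p* to *plane*, in mm."""
    return float(plane.normal @ _as_point(p) - plane.offset)


def reflect_point(p, plane: Plane) -> np.ndarray:
    """Mirror image of *p* across *plane*: p' = p - 2 (n·p - d) n."""
    a = _as_point(p)
    return a - 2.0 * (plane.normal @ a - plane.offset) * plane.normal


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p' = R p + t with R orthonormal, det(R) = +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = _as_point(self.translation)
        if R.shape != (3, 3):
            raise GeometryError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation has negative determinant (reflection)")
        R = R.copy()
        R.flags.writeable = False
        t = t.copy()
        t.flags.writeable = False
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply_point(self, p) -> np.ndarray:
        return self.rotation @ _as_point(p) + self.translation

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_plane(self, plane: Plane) -> Plane:
        n = self.rotation @ plane.normal
        return Plane(n, plane.offset + float(n @ self.translation))

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -(Rt @ self.translation))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def reorientation_transform(fhp: Plane, msp: Plane, origin) -> RigidTransform:
    """Rigid transform reorienting the scene to the standard frame.

    Maps the midsagittal plane onto x = 0 and the Frankfort horizontal plane
    onto a constant-z plane; the given *origin* (projected onto the MSP) maps
    to the new frame origin.  The stored orientation of the plane normals
    defines the frame: the MSP normal becomes +x (patient left) and the FHP
    normal becomes +z (superior), so callers must orient the planes first
    (see :meth:`Plane.oriented_toward`).

    Raises :class:`GeometryInconsistencyError` if the planes are not
    perpendicular to within 1e-6 rad.
    """
    cos_angle = abs(float(fhp.normal @ msp.normal))
    if cos_angle > _PERP_TOL_RAD:
        raise GeometryInconsistencyError(
            f"FHP and MSP are not perpendicular (|cos| = {cos_angle:.3e})"
        )
    ex = msp.normal
    ez = fhp.normal
    ey = np.cross(ez, ex)
    ey = ey / np.linalg.norm(ey)
    # Re-orthogonalize ez against ex to absorb the (tiny) tolerance.
    ez = np.cross(ex, ey)
    R = np.vstack([ex, ey, ez])
    o = _as_point(origin)
    o_proj = o - (msp.normal @ o - msp.offset) * msp.normal
    t = -(R @ o_proj)
    return RigidTransform(R, t)
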