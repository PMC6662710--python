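"""Conventional landmark- and voxel-based bilateral measurements.

The conventional asymmetry workup compares the deviated (Dev) and
non-deviated (N-Dev) sides: ramal length (condylion to gonion midpoint),
body length (gonion midpoint to menton), and hemi-structure surface area and
volume after splitting the structure by a reference plane (AMP or MSP).
Bilateral differences are always Dev minus N-Dev.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import LandmarkSet, Plane, plane_from_points, signed_distance
from .voxel_ops import (
    VoxelMask,
    split_by_plane,
    surface_area_mm2,
    volume_mm3,
)

__all__ = [
    "StructureMeasurements",
    "BilateralDifference",
    "linear_distance",
    "bilateral_difference",
    "sectioning_plane_for_side",
    "measure_structure",
]


def linear_distance(a, b) -> float:
    """Euclidean distance between two points, in mm."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(b - a))


@dataclass(frozen=True)
class BilateralDifference:
    """A Dev-side value, its N-Dev counterpart, and Dev − N-Dev."""

    quantity: str
    dev_value: float
    ndev_value: float
    difference: float


def bilateral_difference(quantity: str, dev_value: float, ndev_value: float) -> BilateralDifference:
    return BilateralDifference(
        quantity=quantity,
        dev_value=float(dev_value),
        ndev_value=float(ndev_value),
        difference=float(dev_value) - float(ndev_value),
    )


@dataclass(frozen=True)
class StructureMeasurements:
    """Per-side measurements of one structure under one reference plane."""

    side: str  # "dev" | "ndev"
    reference_plane: str  # "AMP" | "MSP"
    hemi_surface_mm2: float
    hemi_volume_mm3: float
    ramal_length_mm: Optional[float] = None
    body_length_mm: Optional[float] = None
    ramus_surface_mm2: Optional[float] = None
    ramus_volume_mm3: Optional[float] = None
    body_surface_mm2: Optional[float] = None
    body_volume_mm3: Optional[float] = None
    timepoint: Optional[str] = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def sectioning_plane_for_side(landmarks: LandmarkSet, side: str) -> Plane:
    """Ramus/body sectioning plane of one hemi-mandible.

    The plane through that side's gonion midpoint and the lateral/medial
    junction points, oriented so the ramus (condylion) lies on the positive
    side.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    names = [f"Go_mid_{side}", f"J_lat_{side}", f"J_med_{side}", f"Con_{side}"]
    landmarks.require(names)
    plane = plane_from_points(
        landmarks[f"Go_mid_{side}"],
        landmarks[f"J_lat_{side}"],
        landmarks[f"J_med_{side}"],
    )
    return plane.oriented_toward(landmarks[f"Con_{side}"])


def _anatomical_side(plane_side_sign: int) -> str:
    # positive signed distance = patient left under the package convention
    return "left" if plane_side_sign > 0 else "right"


def measure_structure(
    mask: VoxelMask,
    landmarks: LandmarkSet,
    amp: Plane,
    msp: Plane,
    dev_side: str,
    *,
    surface_mode: str = "face_count",
    exclude_cut_surface: bool = True,
    segments: bool = True,
    timepoint: Optional[str] = None,
) -> list[StructureMeasurements]:
    """Hemi- and segment measurements of a preprocessed structure mask.

    The mask is split by the AMP and by the MSP; each half is measured
    (surface, volume) and labelled dev/ndev from the plane-side sign and the
    given deviation side.  For the AMP split the hemi-mandibles are further
    sectioned into ramus and body using that side's own Go_mid/J_lat/J_med
    plane, and ramal/body lengths are computed from landmarks.

    ``exclude_cut_surface`` removes the artificial flat cut face from
    surface areas (applied uniformly to hemi and segment surfaces).

    Both reference planes must be oriented with normals toward the patient's
    left.  ``dev_side`` is "left" or "right" (from the deviation
    assessment); for a midline subject pass either and read the left/right
    labelling accordingly.
    """
    if dev_side not in ("left", "right"):
        raise ValueError(f"dev_side must be 'left' or 'right', got {dev_side!r}")
    results: list[StructureMeasurements] = []
    for plane_name, plane in (("AMP", amp), ("MSP", msp)):
        pos, neg = split_by_plane(mask, plane)
        for sign, half in ((1, pos), (-1, neg)):
            anat = _anatomical_side(sign)
            label = "dev" if anat == dev_side else "ndev"
            cut = plane if exclude_cut_surface else None
            hemi_surface = surface_area_mm2(half, mode=surface_mode, exclude=cut)
            hemi_volume = volume_mm3(half)
            kwargs: dict = {}
            if plane_name == "AMP":
                landmarks.require([f"Con_{anat}", f"Go_mid_{anat}", "Me"])
                kwargs["ramal_length_mm"] = linear_distance(
                    landmarks[f"Con_{anat}"], landmarks[f"Go_mid_{anat}"]
                )
                kwargs["body_length_mm"] = linear_distance(
                    landmarks[f"Go_mid_{anat}"], landmarks["Me"]
                )
                if segments:
                    section = sectioning_plane_for_side(landmarks, anat)
                    ramus, body = split_by_plane(half, section)
                    cut_seg = section if exclude_cut_surface else None
                    kwargs["ramus_surface_mm2"] = surface_area_mm2(
                        ramus, mode=surface_mode, exclude=cut_seg
                    )
                    kwargs["ramus_volume_mm3"] = volume_mm3(ramus)
                    kwargs["body_surface_mm2"] = surface_area_mm2(
                        body, mode=surface_mode, exclude=cut_seg
                    )
                    kwargs["body_volume_mm3"] = volume_mm3(body)
            results.append(
                StructureMeasurements(
                    side=label,
                    reference_plane=plane_name,
                    hemi_surface_mm2=hemi_surface,
                    hemi_volume_mm3=hemi_volume,
                    timepoint=timepoint,
                    **kwargs,
                )
            )
    return results
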