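"""Mirroring, superimposition, non-overlapping volume and Dice similarity.

The core statistic: split a structure into two halves by a reference plane
(the facial midsagittal plane MSP or the mandible's own median plane AMP),
reflect the left half across that plane onto the right half, and compare the
two voxel sets A (mirrored left) and B (right):

    similarity index (Sørensen–Dice) = 2 |A ∩ B| / (|A| + |B|)

The non-overlapping volume (NOV) is the symmetric difference
|A ∪ B| − |A ∩ B| = |A| + |B| − 2 |A ∩ B|, converted to mm³.  The two are
linked by the exact identity dice = 1 − NOV_voxels / (|A| + |B|).

A value of 1 means the structure is perfectly mirror-symmetric about the
reference plane; 0 means the mirrored half shares no voxel with the other
half.  No re-registration is performed after mirroring: superimposition is
purely by the reference plane, so the index is sensitive to misalignment of
the structure relative to that plane as well as to shape asymmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import LandmarkSet, Plane, signed_distance
from .voxel_ops import GridMismatchError, VoxelMask, split_by_plane

__all__ = [
    "OverlapResult",
    "SegmentDistribution",
    "DeviationAssessment",
    "EmptyOverlapError",
    "mirror_mask",
    "overlap_stats",
    "nonoverlap_mask",
    "mirrored_similarity",
    "segment_distribution",
    "assess_deviation",
]

#: Menton offsets below this are reported as "midline".
MIDLINE_TOL_MM = 1e-6
#: Inclusion rule of the source cohort: menton deviation strictly > 4 mm.
DEFAULT_DEVIATION_THRESHOLD_MM = 4.0


class EmptyOverlapError(ValueError):
    """Dice is undefined: both masks are empty."""


@dataclass(frozen=True)
class OverlapResult:
    """Voxel-overlap summary of two masks A and B on a shared grid."""

    count_a: int
    count_b: int
    count_intersection: int
    count_nonoverlap: int
    dice: float
    nonoverlap_mm3: float

    @classmethod
    def from_counts(cls, count_a: int, count_b: int, count_intersection: int,
                    spacing: float) -> "OverlapResult":
        total = count_a + count_b
        if total == 0:
            raise EmptyOverlapError("both masks empty; similarity index undefined")
        nonoverlap = total - 2 * count_intersection
        return cls(
            count_a=count_a,
            count_b=count_b,
            count_intersection=count_intersection,
            count_nonoverlap=nonoverlap,
            dice=2.0 * count_intersection / total,
            nonoverlap_mm3=nonoverlap * spacing**3,
        )

    def as_dict(self) -> dict:
        return {
            "count_a": self.count_a,
            "count_b": self.count_b,
            "count_intersection": self.count_intersection,
            "count_nonoverlap": self.count_nonoverlap,
            "dice": self.dice,
            "nonoverlap_mm3": self.nonoverlap_mm3,
        }


@dataclass(frozen=True)
class SegmentDistribution:
    """How the non-overlapping volume splits between ramus and body."""

    ramus_fraction: float  # percent of NOV in the ramus segment
    body_fraction: float
    ramus_mm3: float
    body_mm3: float

    def as_dict(self) -> dict:
        return {
            "ramus_fraction": self.ramus_fraction,
            "body_fraction": self.body_fraction,
            "ramus_mm3": self.ramus_mm3,
            "body_mm3": self.body_mm3,
        }


@dataclass(frozen=True)
class DeviationAssessment:
    """Lateral menton deviation from the midsagittal plane."""

    deviation_mm: float
    dev_side: str  # "left" | "right" | "midline"
    included: bool  # deviation strictly greater than the threshold

    def as_dict(self) -> dict:
        return {
            "deviation_mm": self.deviation_mm,
            "dev_side": self.dev_side,
            "included": self.included,
        }


def mirror_mask(mask: VoxelMask, plane: Plane, method: str = "nearest") -> VoxelMask:
    """Reflect a mask across a plane, resampled onto the same grid.

    Each output voxel center is reflected through the plane and the input is
    sampled there.  ``method="nearest"`` (default) preserves binary values
    with no threshold choice; ``method="linear"`` trilinearly interpolates
    the 0/1 field and thresholds at 0.5.  When the plane is a grid mid-plane
    orthogonal to an axis, nearest-neighbour mirroring reduces to an exact
    index flip and is an exact involution.
    """
    if method not in ("nearest", "linear"):
        raise ValueError(f"unknown resampling method: {method!r}")
    nx, ny, nz = mask.shape
    s = mask.spacing
    n = plane.normal
    # reflected world coordinate of voxel (i,j,k): p - 2 (n·p - d) n
    dist = mask.signed_distance_field(plane)
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij", sparse=True
    )
    # reflected position in fractional index units
    fi = ii - (2.0 / s) * dist * n[0]
    fj = jj - (2.0 / s) * dist * n[1]
    fk = kk - (2.0 / s) * dist * n[2]
    if method == "nearest":
        ri = np.rint(fi).astype(np.int64)
        rj = np.rint(fj).astype(np.int64)
        rk = np.rint(fk).astype(np.int64)
        valid = (
            (ri >= 0) & (ri < nx) & (rj >= 0) & (rj < ny) & (rk >= 0) & (rk < nz)
        )
        out = np.zeros(mask.shape, dtype=bool)
        out[valid] = mask.data[ri[valid], rj[valid], rk[valid]]
        return mask.with_data(out)
    # linear: interpolate the binary field, threshold at 0.5
    from scipy.ndimage import map_coordinates

    coords = np.stack(
        [np.broadcast_to(a, mask.shape).ravel() for a in (fi, fj, fk)]
    )
    vals = map_coordinates(
        mask.data.astype(np.float32), coords, order=1, mode="constant", cval=0.0
    )
    return mask.with_data((vals > 0.5).reshape(mask.shape))


def overlap_stats(a: VoxelMask, b: VoxelMask) -> OverlapResult:
    """Voxel counts, non-overlapping volume, and Dice index for two masks.

    The masks must live on the same grid (shape, spacing, origin).  Raises
    :class:`EmptyOverlapError` when both are empty (dice undefined).
    """
    if not a.same_grid(b):
        raise GridMismatchError(
            f"masks on different grids: {a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )
    inter = int((a.data & b.data).sum())
    return OverlapResult.from_counts(a.count, b.count, inter, a.spacing)


def nonoverlap_mask(a: VoxelMask, b: VoxelMask) -> VoxelMask:
    """Voxels in exactly one of the two masks (the NOV region)."""
    if not a.same_grid(b):
        raise GridMismatchError("masks on different grids")
    return a.with_data(a.data ^ b.data)


def mirrored_similarity(
    structure: VoxelMask,
    plane: Plane,
    method: str = "nearest",
    return_masks: bool = False,
):
    """Split a structure by a reference plane, mirror the left (positive-side)
    half onto the right (negative-side) half, and compare the two.

    Returns the :class:`OverlapResult`; with ``return_masks=True`` also the
    mirrored-left and right half masks (in superimposed space) so the NOV
    region can be segmented further.
    """
    left, right = split_by_plane(structure, plane)
    if left.count == 0 or right.count == 0:
        warnings.warn(
            "one half is empty after splitting; similarity index is 0",
            stacklevel=2,
        )
    mirrored_left = mirror_mask(left, plane, method=method)
    result = overlap_stats(mirrored_left, right)
    if return_masks:
        return result, mirrored_left, right
    return result


def segment_distribution(
    nov: VoxelMask, sectioning_plane: Plane, ramus_side: str = "positive"
) -> SegmentDistribution:
    """Distribute non-overlapping voxels between ramus and body segments.

    One sectioning plane (through Go_mid, J_lat, J_med of the superimposed
    hemi-mandible) splits the NOV voxels; ``ramus_side`` states which side of
    the oriented plane is the ramus ("positive" or "negative").
    """
    if ramus_side not in ("positive", "negative"):
        raise ValueError(f"ramus_side must be 'positive' or 'negative', got {ramus_side!r}")
    pos, neg = split_by_plane(nov, sectioning_plane)
    ramus, body = (pos, neg) if ramus_side == "positive" else (neg, pos)
    total = nov.count
    if total == 0:
        warnings.warn("empty non-overlap mask; segment fractions reported as 0",
                      stacklevel=2)
        return SegmentDistribution(0.0, 0.0, 0.0, 0.0)
    s3 = nov.spacing**3
    return SegmentDistribution(
        ramus_fraction=100.0 * ramus.count / total,
        body_fraction=100.0 * body.count / total,
        ramus_mm3=ramus.count * s3,
        body_mm3=body.count * s3,
    )


def assess_deviation(
    landmarks: LandmarkSet,
    msp: Plane,
    threshold_mm: float = DEFAULT_DEVIATION_THRESHOLD_MM,
) -> DeviationAssessment:
    """Classify the deviation (Dev) side from the menton offset to the MSP.

    The MSP must be oriented with its normal toward the patient's left, so a
    positive signed distance of menton (Me) means left deviation.  A subject
    is flagged ``included`` when the deviation strictly exceeds the
    threshold (default 4 mm, the clinical inclusion rule).
    """
    landmarks.require(["Me"])
    d = signed_distance(landmarks["Me"], msp)
    deviation = abs(d)
    if deviation < MIDLINE_TOL_MM:
        side = "midline"
    else:
        side = "left" if d > 0 else "right"
    return DeviationAssessment(
        deviation_mm=deviation,
        dev_side=side,
        included=deviation > threshold_mm,
    )
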