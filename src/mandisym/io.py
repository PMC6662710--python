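"""Volume and landmark file I/O.

NIfTI (.nii/.nii.gz) goes through nibabel; NRRD files and DICOM series
directories go through SimpleITK (with the HU rescale already applied by
the reader).  Grids must be isotropic and axis-aligned: the analysis never
resamples the voxel lattice, so rotated/sheared affines are rejected with a
clear error rather than silently reinterpreted.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import LandmarkSet
from .voxel_ops import HUVolume, VoxelMask

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "read_landmarks",
]

_ISO_RTOL = 1e-4


def _check_isotropic(spacing: np.ndarray) -> float:
    spacing = np.asarray(spacing, dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=_ISO_RTOL):
        raise ValueError(
            f"anisotropic voxel spacing {tuple(spacing)} is not supported; "
            "resample to an isotropic grid first"
        )
    return float(spacing[0])


def _from_nifti(path: Path) -> HUVolume:
    img = nib.load(str(path))
    affine = img.affine
    lin = affine[:3, :3]
    diag = np.diag(lin).copy()
    if not np.allclose(lin, np.diag(diag), atol=1e-6 * max(1.0, np.abs(diag).max())):
        raise ValueError(
            f"{path}: only axis-aligned (diagonal-affine) NIfTI volumes are "
            "supported; reorient/resample the image first"
        )
    if np.any(diag <= 0):
        raise ValueError(f"{path}: negative/zero affine scales are not supported")
    spacing = _check_isotropic(diag)
    origin = affine[:3, 3].astype(float)
    data = np.asarray(img.dataobj, dtype=float)
    return HUVolume(data, spacing, origin)


def _from_sitk(path: Path) -> HUVolume:
    import SimpleITK as sitk

    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(path))
        if not files:
            raise ValueError(f"no DICOM series found in {path}")
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        img = sitk.ReadImage(str(path))
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            f"{path}: non-identity direction matrix; reorient the image first"
        )
    spacing = _check_isotropic(np.array(img.GetSpacing()))
    origin = np.array(img.GetOrigin(), dtype=float)
    # sitk arrays are indexed (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).astype(float).transpose(2, 1, 0)
    return HUVolume(data, spacing, origin)


def read_volume(path: str | Path) -> HUVolume:
    """Read a scalar HU volume from NIfTI, NRRD, or a DICOM series directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _from_nifti(path)
    if name.endswith(".nrrd") or path.is_dir():
        return _from_sitk(path)
    raise ValueError(f"unrecognised volume format: {path}")


def _nifti_affine(spacing: float, origin: np.ndarray) -> np.ndarray:
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = origin
    return affine


def write_volume(volume: HUVolume, path: str | Path) -> None:
    """Write a HU volume as NIfTI (float32)."""
    img = nib.Nifti1Image(
        volume.data.astype(np.float32),
        _nifti_affine(volume.spacing, volume.origin),
    )
    nib.save(img, str(path))


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a binary mask as unsigned 8-bit NIfTI."""
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8),
        _nifti_affine(mask.spacing, mask.origin),
    )
    nib.save(img, str(path))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a named-landmark file (JSON object name → [x, y, z], or CSV with
    columns name,x,y,z); coordinates in mm, world frame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    return LandmarkSet.from_file(path)
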