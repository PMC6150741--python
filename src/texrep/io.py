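"""NIfTI and manifest I/O.

Volumes and masks are stored as ``.nii.gz`` on disk in NIfTI ``(x, y, z)``
axis order; in memory this package uses ``(z, y, x)``, so arrays are
transposed on the way in and out. Masks are 0/1 uint8 volumes on the same
grid. A cohort is described by a CSV manifest with columns
``subject_id, day, volume_path, mask_path, reader_id``.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ShapeMismatchError, ValidationError
from .volume import ImageVolume, RoiMask

MANIFEST_COLUMNS = ["subject_id", "day", "volume_path", "mask_path", "reader_id"]


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = voxel_size
    return np.diag([dx, dy, dz, 1.0])


def write_study(volume: ImageVolume, mask: RoiMask, path: str | os.PathLike) -> tuple[str, str]:
    """Write a (volume, mask) pair as ``<path>.nii.gz`` and ``<path>_mask.nii.gz``.

    Returns the two file paths written. Intensities are stored as float32
    (lossless round-trip within float32 precision); the mask round-trips
    exactly.
    """
    if volume.shape != mask.shape:
        raise ShapeMismatchError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol_path = path.with_name(path.name + ".nii.gz")
    mask_path = path.with_name(path.name + "_mask.nii.gz")
    aff = _affine(volume.voxel_size)
    # (z, y, x) -> (x, y, z) for NIfTI
    nib.save(nib.Nifti1Image(volume.data.T.astype(np.float32), aff), str(vol_path))
    nib.save(nib.Nifti1Image(mask.data.T.astype(np.uint8), aff), str(mask_path))
    return str(vol_path), str(mask_path)


def write_mask(mask: RoiMask, path: str | os.PathLike, voxel_size: tuple[float, float, float]) -> str:
    """Write a standalone mask volume (uint8 NIfTI) and return its path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(mask.data.T.astype(np.uint8), _affine(voxel_size)), str(path))
    return str(path)


def read_study(volume_path: str | os.PathLike, mask_path: str | os.PathLike) -> tuple[ImageVolume, RoiMask]:
    """Read a (volume, mask) NIfTI pair written by :func:`write_study`."""
    volume_path, mask_path = Path(volume_path), Path(mask_path)
    if not volume_path.exists():
        raise FileNotFoundError(f"volume file not found: {volume_path}")
    if not mask_path.exists():
        raise FileNotFoundError(f"mask file not found: {mask_path}")
    vimg = nib.load(str(volume_path))
    mimg = nib.load(str(mask_path))
    zooms = vimg.header.get_zooms()[:3]  # (dx, dy, dz)
    voxel_size = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    vdata = np.asarray(vimg.dataobj, dtype=float).T
    mdata = np.asarray(mimg.dataobj).T
    if vdata.shape != mdata.shape:
        raise ShapeMismatchError(
            f"volume shape {vdata.shape} != mask shape {mdata.shape}"
        )
    return ImageVolume(vdata, voxel_size), RoiMask(mdata)


def append_manifest_row(
    manifest_path: str | os.PathLike,
    subject_id: str,
    day: int,
    volume_path: str,
    mask_path: str,
    reader_id: int = 1,
) -> None:
    """Append one study row to the cohort manifest, creating it if absent."""
    manifest_path = Path(manifest_path)
    row = pd.DataFrame(
        [[subject_id, day, volume_path, mask_path, reader_id]], columns=MANIFEST_COLUMNS
    )
    header = not manifest_path.exists()
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    row.to_csv(manifest_path, mode="a", header=header, index=False)


def read_manifest(manifest_path: str | os.PathLike) -> pd.DataFrame:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    return df


def validate_pairing(manifest: pd.DataFrame) -> None:
    """Require exactly one day-1 and one day-2 study per (subject, reader)."""
    for (subject, reader), grp in manifest.groupby(["subject_id", "reader_id"]):
        days = sorted(grp["day"].tolist())
        if days != [1, 2]:
            raise ValidationError(
                f"subject {subject!r} reader {reader!r} has days {days}; "
                "expected exactly [1, 2]"
            )
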