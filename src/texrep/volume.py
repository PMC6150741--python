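"""Core in-memory containers for image volumes, ROI masks and quantized volumes.

Axis convention
---------------
All arrays are indexed ``(z, y, x)`` with 0-based voxel indices: axis 0 is the
through-plane (slice) direction, axes 1 and 2 are in-plane.  ``voxel_size``
follows the same order, in millimetres, so ``voxel_size[0]`` is the slice
pitch (slice thickness plus intersection gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyMaskError, ShapeMismatchError


@dataclass
class ImageVolume:
    """A 3D real-valued intensity lattice with voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensities in arbitrary MR units. Must be finite.
    voxel_size : tuple of float
        Voxel pitch in mm as ``(dz, dy, dx)``; strictly positive.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ShapeMismatchError(f"volume must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class RoiMask:
    """A binary region-of-interest on the same grid as its paired volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ShapeMismatchError(f"mask must be 3D, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self) -> None:
        if not self.data.any():
            raise EmptyMaskError("ROI mask contains no voxels")


def check_same_grid(volume: ImageVolume, mask: RoiMask) -> None:
    if volume.shape != mask.shape:
        raise ShapeMismatchError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )


@dataclass
class QuantizedVolume:
    """ROI-masked lattice of integer gray bins.

    In-mask voxels carry bin values in ``1..n_bins``; out-of-mask voxels carry
    the sentinel 0.  ``bin_edges`` (length ``n_bins + 1``, strictly increasing)
    records the original-intensity bounds of each bin, so bin centers in
    original units remain recoverable after quantization.
    """

    data: np.ndarray
    n_bins: int
    bin_edges: np.ndarray
    voxel_size: tuple[float, float, float]
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int32)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        inside = self.data[self.data > 0]
        if inside.size and inside.max() > self.n_bins:
            raise ValueError("in-mask bin values exceed n_bins")
        if len(self.bin_edges) != self.n_bins + 1:
            raise ValueError("bin_edges must have n_bins + 1 entries")

    @property
    def mask(self) -> np.ndarray:
        return self.data > 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def bin_centers(self) -> np.ndarray:
        """Original-intensity center of each bin, length ``n_bins``."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def masked_values(self) -> np.ndarray:
        """Flat array of in-mask bin values (1..n_bins)."""
        return self.data[self.mask]
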