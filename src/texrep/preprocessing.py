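"""Segmentation-to-quantization chain.

The analysis chain mirrors the standard MR texture workflow: a per-slice ROI
segmentation is assembled into a whole-tumor composite volume, a smoothing
filter is applied in-plane, and intensities are quantized to a fixed number of
equal-width gray bins over the in-mask intensity range.

Filtering is strictly 2D per slice: the acquisition geometry this package
emulates has a 7.8 mm through-plane pitch (6 mm sections + 1.8 mm gap) versus
~0.7 mm in-plane, so 3D filtering across slices would mix anatomically distant
tissue. No spatial resampling is performed; anisotropy is carried as metadata.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import ConfigError, EmptyMaskError
from .volume import ImageVolume, QuantizedVolume, RoiMask, check_same_grid

DEFAULT_BINS = 32

SMOOTHING_MODES = ("none", "gaussian", "log")


def assemble_tumor_volume(
    volume: ImageVolume, mask: RoiMask, pad: int = 1
) -> tuple[ImageVolume, RoiMask]:
    """Crop a (volume, mask) pair to the mask bounding box plus ``pad`` voxels.

    Slices (and in-plane rows/columns) entirely outside the padded bounding
    box are dropped; the in-mask voxel count is conserved exactly.
    """
    check_same_grid(volume, mask)
    mask.require_nonempty()
    idx = np.nonzero(mask.data)
    slices = []
    for ax in range(3):
        lo = max(int(idx[ax].min()) - pad, 0)
        hi = min(int(idx[ax].max()) + pad + 1, mask.shape[ax])
        slices.append(slice(lo, hi))
    sl = tuple(slices)
    return (
        ImageVolume(volume.data[sl].copy(), volume.voxel_size),
        RoiMask(mask.data[sl].copy()),
    )


def apply_smoothing_filter(
    volume: ImageVolume, mode: str = "gaussian", scale_mm: float = 2.0
) -> ImageVolume:
    """Apply the configured in-plane smoothing filter slice by slice.

    Parameters
    ----------
    mode : {"none", "gaussian", "log"}
        ``gaussian`` is a 2D Gaussian of standard deviation ``scale_mm``;
        ``log`` is the (negated) Laplacian-of-Gaussian at the same scale;
        ``none`` returns the input unchanged.
    scale_mm : float
        Filter scale in millimetres, converted per axis to voxel units.
    """
    if mode not in SMOOTHING_MODES:
        raise ConfigError(f"unknown smoothing mode {mode!r}; expected one of {SMOOTHING_MODES}")
    if mode == "none":
        return volume
    if scale_mm <= 0:
        raise ConfigError(f"scale_mm must be positive for mode {mode!r}, got {scale_mm}")
    _, dy, dx = volume.voxel_size
    sigma = (scale_mm / dy, scale_mm / dx)
    out = np.empty_like(volume.data)
    for k in range(volume.shape[0]):
        if mode == "gaussian":
            out[k] = ndimage.gaussian_filter(volume.data[k], sigma=sigma, mode="reflect")
        else:
            out[k] = -ndimage.gaussian_laplace(volume.data[k], sigma=sigma, mode="reflect")
    return ImageVolume(out, volume.voxel_size)


def quantize(volume: ImageVolume, mask: RoiMask, n_bins: int = DEFAULT_BINS) -> QuantizedVolume:
    """Quantize in-mask intensities to ``n_bins`` equal-width gray bins.

    Bins span the in-mask ``[min, max]`` intensity range (ROI-relative
    binning), the top bin is right-closed so the maximum maps to bin
    ``n_bins``, and binning is monotone in intensity.  The mapping is
    invariant to positive affine rescaling of the intensities.  A constant
    in-mask region maps every voxel to bin 1 and sets the ``constant_input``
    flag rather than raising.
    """
    if n_bins < 2:
        raise ConfigError(f"n_bins must be >= 2, got {n_bins}")
    check_same_grid(volume, mask)
    mask.require_nonempty()
    inside = volume.data[mask.data]
    lo, hi = float(inside.min()), float(inside.max())
    flags: dict = {}
    out = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        out[mask.data] = 1
        flags["constant_input"] = "in-mask intensities are constant; all voxels in bin 1"
        edges = lo + np.arange(n_bins + 1, dtype=float)  # degenerate but increasing
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        width = (hi - lo) / n_bins
        bins = np.floor((volume.data - lo) / width).astype(np.int64) + 1
        np.clip(bins, 1, n_bins, out=bins)
        out[mask.data] = bins[mask.data]
    return QuantizedVolume(
        data=out,
        n_bins=n_bins,
        bin_edges=edges,
        voxel_size=volume.voxel_size,
        flags=flags,
    )


def preprocess(
    volume: ImageVolume,
    mask: RoiMask,
    *,
    filter_mode: str = "gaussian",
    filter_scale_mm: float = 2.0,
    n_bins: int = DEFAULT_BINS,
) -> QuantizedVolume:
    """Full chain: smooth in-plane, crop to the tumor, quantize to gray bins."""
    smoothed = apply_smoothing_filter(volume, mode=filter_mode, scale_mm=filter_scale_mm)
    cropped, cmask = assemble_tumor_volume(smoothed, mask)
    return quantize(cropped, cmask, n_bins=n_bins)
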