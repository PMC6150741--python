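from __future__ import annotations

import numpy as np
import pytest

from texrep.volume import ImageVolume, QuantizedVolume, RoiMask

VOXEL_SIZE = (7.8, 0.68, 0.68)  # (dz, dy, dx) mm


def make_quantized(data, n_bins=None, mask=None, bin_edges=None):
    """QuantizedVolume from an integer array; bin centers default to 1..G."""
    data = np.asarray(data, dtype=np.int32)
    if mask is not None:
        data = np.where(np.asarray(mask, bool), data, 0)
    g = int(n_bins if n_bins is not None else max(int(data.max()), 1))
    if bin_edges is None:
        bin_edges = np.arange(0.5, g + 1.0)  # centers at 1..G
    return QuantizedVolume(data, g, bin_edges, VOXEL_SIZE)


def random_quantized(rng, shape, n_bins, p_mask=1.0):
    data = rng.integers(1, n_bins + 1, size=shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask.flat[0] = True
    return make_quantized(data, n_bins=n_bins, mask=mask), mask


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_volume_pair():
    """A small smooth volume + ellipsoid-ish mask for pipeline-level tests."""
    rng = np.random.default_rng(7)
    data = 200.0 + 40.0 * rng.standard_normal((6, 40, 40))
    z, y, x = np.ogrid[:6, :40, :40]
    mask = ((z - 2.5) / 2.2) ** 2 + ((y - 20) / 14) ** 2 + ((x - 20) / 14) ** 2 <= 1
    return ImageVolume(data, VOXEL_SIZE), RoiMask(mask)
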