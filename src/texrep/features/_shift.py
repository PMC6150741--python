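"""Array-offset helpers shared by the texture-matrix builders."""

from __future__ import annotations

import numpy as np


def offset_slices(shape, offset):
    """Slice pairs aligning each voxel ``v`` (src) with ``v + offset`` (dst).

    Returns ``(src, dst)`` tuples of slices such that ``a[src]`` and
    ``a[dst]`` enumerate all in-grid pairs at the given displacement.
    """
    src, dst = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def shifted(arr: np.ndarray, offset, fill=0) -> np.ndarray:
    """Return ``out`` with ``out[v] = arr[v + offset]`` (``fill`` off-grid)."""
    out = np.full_like(arr, fill)
    src, dst = offset_slices(arr.shape, tuple(-d for d in offset))
    out[dst] = arr[src]
    return out
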