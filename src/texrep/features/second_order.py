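"""Local second-order features: gray-level co-occurrence (GLCM) and
gray-level difference (GLDM) matrices.

Both matrices describe adjacent in-plane voxel pairs.  By default pairs are
taken at distance 1 along the four in-plane directions (0,1), (1,0), (1,1),
(1,-1), pooled across directions and slices into a single matrix before
normalization (better conditioned than per-direction averaging on small
masked regions); only pairs with both voxels in-mask contribute.  The GLCM is
symmetrized.  Gray-level indices in moment-type features are the bin numbers
1..G.  Entropies are in bits with 0 log 0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import DegenerateInputError
from ..volume import QuantizedVolume
from ._shift import offset_slices

# (dz, dy, dx) in-plane displacement set, closed under 90-degree rotation
INPLANE_DIRECTIONS = ((0, 0, 1), (0, 1, 0), (0, 1, 1), (0, 1, -1))

GLCM_FEATURES = (
    "glcm_entropy",
    "glcm_energy",
    "glcm_contrast",
    "glcm_homogeneity",
    "glcm_idm",
    "glcm_correlation",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_sum_entropy",
    "glcm_difference_entropy",
    "glcm_sum_average",
    "glcm_dissimilarity",
)

GLDM_FEATURES = ("gldm_entropy", "gldm_contrast", "gldm_mean")


@dataclass
class GLCM:
    """Symmetric joint probability ``p[i-1, j-1]`` of gray pairs (i, j)."""

    p: np.ndarray
    n_bins: int
    n_pairs: int
    distance: int = 1
    directions: tuple = INPLANE_DIRECTIONS


@dataclass
class GLDM:
    """Probability ``pd[k]`` of absolute gray difference k = 0..G-1."""

    pd: np.ndarray
    n_bins: int
    n_pairs: int
    distance: int = 1
    directions: tuple = INPLANE_DIRECTIONS


@dataclass
class SecondOrderFeatures:
    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)


def _pair_levels(q: QuantizedVolume, distance: int, directions):
    """Concatenated (level_a, level_b) arrays over all in-mask pairs."""
    if distance < 1:
        raise DegenerateInputError(f"distance must be >= 1, got {distance}")
    a_all, b_all = [], []
    mask = q.mask
    for d in directions:
        off = tuple(distance * c for c in d)
        src, dst = offset_slices(q.shape, off)
        valid = mask[src] & mask[dst]
        a_all.append(q.data[src][valid])
        b_all.append(q.data[dst][valid])
    a = np.concatenate(a_all)
    b = np.concatenate(b_all)
    if a.size == 0:
        raise DegenerateInputError(
            "no valid in-mask voxel pairs at the requested displacement"
        )
    return a, b


def compute_glcm(
    q: QuantizedVolume, distance: int = 1, directions=INPLANE_DIRECTIONS
) -> GLCM:
    a, b = _pair_levels(q, distance, directions)
    g = q.n_bins
    counts = np.bincount((a - 1) * g + (b - 1), minlength=g * g).reshape(g, g)
    counts = counts + counts.T  # symmetrize
    p = counts / counts.sum()
    return GLCM(p=p, n_bins=g, n_pairs=int(a.size), distance=distance, directions=tuple(directions))


def compute_gldm(
    q: QuantizedVolume, distance: int = 1, directions=INPLANE_DIRECTIONS
) -> GLDM:
    a, b = _pair_levels(q, distance, directions)
    g = q.n_bins
    counts = np.bincount(np.abs(a - b), minlength=g)
    pd = counts / counts.sum()
    return GLDM(pd=pd, n_bins=g, n_pairs=int(a.size), distance=distance, directions=tuple(directions))


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def glcm_features(m: GLCM) -> SecondOrderFeatures:
    g = m.n_bins
    p = m.p
    flags: dict[str, str] = {}
    i = np.arange(1, g + 1)[:, None]
    j = np.arange(1, g + 1)[None, :]
    diff = i - j
    values = {
        "glcm_entropy": _entropy_bits(p),
        "glcm_energy": float((p**2).sum()),
        "glcm_contrast": float((p * diff**2).sum()),
        "glcm_homogeneity": float((p / (1 + np.abs(diff))).sum()),
        "glcm_idm": float((p / (1 + diff**2)).sum()),
        "glcm_dissimilarity": float((p * np.abs(diff)).sum()),
    }
    # marginals (symmetric matrix: both marginals coincide)
    pi = p.sum(axis=1)
    mu_i = float((np.arange(1, g + 1) * pi).sum())
    var_i = float(((np.arange(1, g + 1) - mu_i) ** 2 * pi).sum())
    if var_i > 0:
        values["glcm_correlation"] = float(
            ((i - mu_i) * (j - mu_i) * p).sum() / var_i
        )
    else:
        values["glcm_correlation"] = 0.0
        flags["glcm_correlation"] = "undefined: zero marginal variance"
    dev = (i - mu_i) + (j - mu_i)
    values["glcm_cluster_shade"] = float((p * dev**3).sum())
    values["glcm_cluster_prominence"] = float((p * dev**4).sum())
    # sum (i+j) and difference |i-j| marginal distributions
    ij_sum = (i + j).ravel()
    p_sum = np.bincount(ij_sum, weights=p.ravel(), minlength=2 * g + 1)[2:]
    ij_diff = np.abs(diff).ravel()
    p_diff = np.bincount(ij_diff, weights=p.ravel(), minlength=g)
    values["glcm_sum_entropy"] = _entropy_bits(p_sum)
    values["glcm_difference_entropy"] = _entropy_bits(p_diff)
    values["glcm_sum_average"] = float((np.arange(2, 2 * g + 1) * p_sum).sum())
    return SecondOrderFeatures(values=values, flags=flags)


def gldm_features(m: GLDM) -> SecondOrderFeatures:
    k = np.arange(m.n_bins)
    pd = m.pd
    values = {
        "gldm_entropy": _entropy_bits(pd),
        "gldm_contrast": float((k**2 * pd).sum()),
        "gldm_mean": float((k * pd).sum()),
    }
    return SecondOrderFeatures(values=values)


def second_order_features(
    q: QuantizedVolume, distance: int = 1, directions=INPLANE_DIRECTIONS
) -> SecondOrderFeatures:
    """Compute the full GLCM + GLDM feature panel for one quantized volume."""
    glcm = glcm_features(compute_glcm(q, distance, directions))
    gldm = gldm_features(compute_gldm(q, distance, directions))
    return SecondOrderFeatures(
        values={**glcm.values, **gldm.values},
        flags={**glcm.flags, **gldm.flags},
    )
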