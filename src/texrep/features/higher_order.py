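"""High-order multiplanar features: NGTDM, gray-level run-length (GLRLM) and
gray-level zone-size (GLZSM) families.

These examine relationships between neighboring voxels across imaging planes:
by default the NGTDM uses the 26-voxel 3D neighborhood, the GLZSM uses
26-connectivity for zone growing, and the GLRLM pools maximal runs over the
13 unique 3D directions.  In-plane-only variants (8-neighborhood,
8-connectivity, 4 directions) are available for thick-slice geometries.

Formulations follow the classical definitions (Amadasun-King NGTDM,
Galloway/Chu run-length, Thibault zone-size): matrices hold raw counts and
normalization happens at the feature level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..errors import EmptyMaskError
from ..volume import QuantizedVolume
from ._shift import offset_slices, shifted

NGTDM_EPS = 1e-12

NGTDM_FEATURES = ("ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness", "ngtdm_complexity")

GLRL_FEATURES = (
    "glrl_sre",
    "glrl_lre",
    "glrl_intensity_variability",
    "glrl_run_length_variability",
    "glrl_run_percentage",
    "glrl_low_gray_run_emphasis",
    "glrl_high_gray_run_emphasis",
)

GLZSM_FEATURES = (
    "glzsm_short_zone_emphasis",
    "glzsm_large_zone_emphasis",
    "glzsm_intensity_nonuniformity",
    "glzsm_intensity_variability",
    "glzsm_size_zone_variability",
    "glzsm_zone_percentage",
    "glzsm_low_gray_zone_emphasis",
    "glzsm_high_gray_zone_emphasis",
    "glzsm_size_variance",
)


def run_directions_3d() -> tuple[tuple[int, int, int], ...]:
    """The 13 unique 3D directions (one per opposite pair)."""
    dirs = []
    for dz in (0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if dz == 0 and (dy < 0 or (dy == 0 and dx < 0)):
                    continue
                dirs.append((dz, dy, dx))
    return tuple(dirs)


RUN_DIRECTIONS_3D = run_directions_3d()
RUN_DIRECTIONS_2D = ((0, 0, 1), (0, 1, 0), (0, 1, 1), (0, 1, -1))


@dataclass
class NGTDM:
    """s[g]: summed |gray - neighborhood mean| per level; p[g]: occupancy."""

    s: np.ndarray
    p: np.ndarray
    n_valid: int
    n_bins: int


@dataclass
class GLRLM:
    """r[g-1, l-1]: number of maximal runs of level g and length l (pooled)."""

    r: np.ndarray
    n_bins: int
    n_voxels: int
    n_directions: int


@dataclass
class GLZSM:
    """Zone list representation: gray level and size of each connected zone."""

    zone_gray: np.ndarray
    zone_size: np.ndarray
    n_bins: int
    n_voxels: int


@dataclass
class HighOrderFeatures:
    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)


# -------------------------------------------------------------------- NGTDM


def compute_ngtdm(q: QuantizedVolume, neighborhood: str = "26") -> NGTDM:
    """Neighborhood gray-tone difference matrix.

    The neighborhood mean of each voxel excludes the center and any
    out-of-mask voxels; voxels with no in-mask neighbor do not contribute.
    """
    if neighborhood == "26":
        kernel = np.ones((3, 3, 3))
        kernel[1, 1, 1] = 0
    elif neighborhood == "8-in-plane":
        kernel = np.ones((1, 3, 3))
        kernel[0, 1, 1] = 0
    else:
        raise ValueError(f"unknown neighborhood {neighborhood!r}")
    mask = q.mask
    if not mask.any():
        raise EmptyMaskError("empty mask")
    vals = np.where(mask, q.data, 0).astype(float)
    nbr_sum = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (nbr_cnt > 0.5)
    if not valid.any():
        raise EmptyMaskError("no voxel has an in-mask neighbor")
    dev = np.abs(q.data[valid] - nbr_sum[valid] / nbr_cnt[valid])
    levels = q.data[valid]
    s = np.bincount(levels, weights=dev, minlength=q.n_bins + 1)[1:]
    counts = np.bincount(levels, minlength=q.n_bins + 1)[1:]
    n_valid = int(valid.sum())
    return NGTDM(s=s, p=counts / n_valid, n_valid=n_valid, n_bins=q.n_bins)


def ngtdm_features(m: NGTDM) -> HighOrderFeatures:
    flags: dict[str, str] = {}
    g = np.arange(1, m.n_bins + 1)
    occ = m.p > 0
    ng = int(occ.sum())
    ps = float((m.p * m.s).sum())
    coarseness = min(1.0 / (NGTDM_EPS + ps), 1.0 / NGTDM_EPS)
    gi = g[occ][:, None]
    gj = g[occ][None, :]
    pi = m.p[occ][:, None]
    pj = m.p[occ][None, :]
    si = m.s[occ][:, None]
    sj = m.s[occ][None, :]
    if ng > 1:
        contrast = float(
            (pi * pj * (gi - gj) ** 2).sum() / (ng * (ng - 1)) * m.s.sum() / m.n_valid
        )
    else:
        contrast = 0.0
        flags["ngtdm_contrast"] = "single occupied gray level"
    busy_den = float(np.abs(gi * pi - gj * pj).sum())
    if busy_den > 0:
        busyness = ps / busy_den
    else:
        busyness = 0.0
        flags["ngtdm_busyness"] = "degenerate: zero busyness denominator"
    complexity = float(
        (np.abs(gi - gj) * (pi * si + pj * sj) / (m.n_valid * (pi + pj))).sum()
    )
    return HighOrderFeatures(
        values={
            "ngtdm_coarseness": coarseness,
            "ngtdm_contrast": contrast,
            "ngtdm_busyness": busyness,
            "ngtdm_complexity": complexity,
        },
        flags=flags,
    )


# -------------------------------------------------------------------- GLRLM


def compute_glrlm(q: QuantizedVolume, directions=RUN_DIRECTIONS_3D) -> GLRLM:
    """Pooled maximal-run counts within the mask, per gray level and length."""
    mask = q.mask
    if not mask.any():
        raise EmptyMaskError("empty mask")
    n_voxels = int(mask.sum())
    max_len = max(q.shape)
    r = np.zeros((q.n_bins, max_len), dtype=np.int64)
    for d in directions:
        # connect[v]: v continues the run from v - d
        connect = np.zeros(q.shape, dtype=bool)
        src, dst = offset_slices(q.shape, d)
        connect[dst] = mask[dst] & mask[src] & (q.data[dst] == q.data[src])
        starts = mask & ~connect
        lengths = starts.astype(np.int64)
        frontier = starts.copy()
        k = 1
        while frontier.any():
            nxt = shifted(connect, tuple(k * c for c in d))
            frontier &= nxt
            lengths[frontier] += 1
            k += 1
        gl = q.data[starts] - 1
        ln = lengths[starts] - 1
        np.add.at(r, (gl, ln), 1)
    total = int((r * np.arange(1, max_len + 1)[None, :]).sum())
    assert total == n_voxels * len(directions), "run mass conservation violated"
    return GLRLM(r=r, n_bins=q.n_bins, n_voxels=n_voxels, n_directions=len(directions))


def glrlm_features(m: GLRLM) -> HighOrderFeatures:
    r = m.r.astype(float)
    nr = r.sum()
    g = np.arange(1, m.n_bins + 1)[:, None].astype(float)
    l = np.arange(1, r.shape[1] + 1)[None, :].astype(float)
    values = {
        "glrl_sre": float((r / l**2).sum() / nr),
        "glrl_lre": float((r * l**2).sum() / nr),
        "glrl_intensity_variability": float((r.sum(axis=1) ** 2).sum() / nr),
        "glrl_run_length_variability": float((r.sum(axis=0) ** 2).sum() / nr),
        "glrl_run_percentage": float(nr / (m.n_voxels * m.n_directions)),
        "glrl_low_gray_run_emphasis": float((r / g**2).sum() / nr),
        "glrl_high_gray_run_emphasis": float((r * g**2).sum() / nr),
    }
    return HighOrderFeatures(values=values)


# -------------------------------------------------------------------- GLZSM


def compute_glzsm(q: QuantizedVolume, connectivity: int = 26) -> GLZSM:
    """Connected iso-gray-level zones of the in-mask volume."""
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError(f"connectivity must be 26 or 6, got {connectivity}")
    mask = q.mask
    if not mask.any():
        raise EmptyMaskError("empty mask")
    zone_gray, zone_size = [], []
    for g in np.unique(q.data[mask]):
        labels, n = ndimage.label(mask & (q.data == g), structure=structure)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            zone_gray.extend([int(g)] * n)
            zone_size.extend(sizes.tolist())
    zone_gray = np.asarray(zone_gray, dtype=np.int64)
    zone_size = np.asarray(zone_size, dtype=np.int64)
    assert zone_size.sum() == mask.sum(), "zone mass conservation violated"
    return GLZSM(zone_gray=zone_gray, zone_size=zone_size, n_bins=q.n_bins, n_voxels=int(mask.sum()))


def glzsm_features(m: GLZSM) -> HighOrderFeatures:
    g = m.zone_gray.astype(float)
    s = m.zone_size.astype(float)
    nz = float(len(s))
    n_per_gray = np.bincount(m.zone_gray)
    n_per_size = np.bincount(m.zone_size)
    values = {
        "glzsm_short_zone_emphasis": float((1.0 / s**2).sum() / nz),
        "glzsm_large_zone_emphasis": float((s**2).sum() / nz),
        "glzsm_intensity_nonuniformity": float((n_per_gray.astype(float) ** 2).sum() / nz),
        "glzsm_intensity_variability": float(((g - g.mean()) ** 2).mean()),
        "glzsm_size_zone_variability": float((n_per_size.astype(float) ** 2).sum() / nz),
        "glzsm_zone_percentage": float(nz / m.n_voxels),
        "glzsm_low_gray_zone_emphasis": float((1.0 / g**2).sum() / nz),
        "glzsm_high_gray_zone_emphasis": float((g**2).sum() / nz),
        "glzsm_size_variance": float(((s - s.mean()) ** 2).mean()),
    }
    return HighOrderFeatures(values=values)


def higher_order_features(
    q: QuantizedVolume,
    *,
    neighborhood: str = "26",
    run_directions=RUN_DIRECTIONS_3D,
    connectivity: int = 26,
) -> HighOrderFeatures:
    """Compute the full NGTDM + GLRL + GLZSM panel for one quantized volume."""
    parts = [
        ngtdm_features(compute_ngtdm(q, neighborhood)),
        glrlm_features(compute_glrlm(q, run_directions)),
        glzsm_features(compute_glzsm(q, connectivity)),
    ]
    values: dict[str, float] = {}
    flags: dict[str, str] = {}
    for part in parts:
        values.update(part.values)
        flags.update(part.flags)
    return HighOrderFeatures(values=values, flags=flags)
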