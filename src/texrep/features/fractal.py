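"""Global model-based (fractal) features.

Three estimators operate on the quantized tumor volume, treating the gray
level as a height field over each axial slice:

* ``boxcount_fd`` — per-slice differential box-counting dimension
  (Sarkar-Chaudhuri style), aggregated as mean and SD across slices.  A flat
  filled region recovers the analytic limit FD = 2, a one-pixel line FD = 1.
* ``lacunarity`` — gliding-box lacunarity ``1 + var(M)/mean(M)^2`` of the
  in-mask box mass (sum of gray levels), averaged over box sizes.  A constant
  image has lacunarity exactly 1.
* ``hurst_exponent`` — rescaled-range (R/S) estimate over in-mask 1D
  intensity profiles (rows and columns), with the Anis-Lloyd/Peters
  finite-sample expectation correction so that white noise recovers H = 0.5
  without the small-window bias of the naive slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from ..errors import EmptyMaskError
from ..volume import QuantizedVolume

FRACTAL_FEATURES = (
    "fractal_fd_mean",
    "fractal_fd_sd",
    "fractal_lacunarity",
    "fractal_hurst",
)

DEFAULT_BOX_SCALES = (2, 4, 8, 16)
DEFAULT_LACUNARITY_BOXES = (2, 4, 8)
MIN_PROFILE_LEN = 8


@dataclass
class FractalFeatures:
    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------- box counting


def _slice_fd(values: np.ndarray, mask: np.ndarray, n_bins: int, scales) -> float | None:
    """Differential box-counting dimension of one masked slice, or None."""
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        return None
    y0, y1 = idx[0].min(), idx[0].max() + 1
    x0, x1 = idx[1].min(), idx[1].max() + 1
    sub = values[y0:y1, x0:x1].astype(float)
    msk = mask[y0:y1, x0:x1]
    m_side = max(sub.shape)
    usable = [s for s in scales if s <= m_side]
    if len(usable) < 4:
        return None  # slice too small for a stable log-log fit
    log_inv_s, log_n = [], []
    for s in usable:
        h = s * n_bins / m_side  # box height in gray-level units
        ny = -(-sub.shape[0] // s)
        nx = -(-sub.shape[1] // s)
        vmax = np.full((ny * s, nx * s), -np.inf)
        vmin = np.full((ny * s, nx * s), np.inf)
        vmax[: sub.shape[0], : sub.shape[1]] = np.where(msk, sub, -np.inf)
        vmin[: sub.shape[0], : sub.shape[1]] = np.where(msk, sub, np.inf)
        bmax = vmax.reshape(ny, s, nx, s).max(axis=(1, 3))
        bmin = vmin.reshape(ny, s, nx, s).min(axis=(1, 3))
        occupied = np.isfinite(bmax)
        n_boxes = (
            np.floor(bmax[occupied] / h) - np.floor(bmin[occupied] / h) + 1
        ).sum()
        log_inv_s.append(np.log(1.0 / s))
        log_n.append(np.log(n_boxes))
    slope = np.polyfit(log_inv_s, log_n, 1)[0]
    return float(slope)


def boxcount_fd(q: QuantizedVolume, scales=DEFAULT_BOX_SCALES) -> tuple[float, float, dict]:
    """Per-slice differential box-counting FD: returns (fd_mean, fd_sd, flags)."""
    flags: dict[str, str] = {}
    fds = []
    for k in range(q.shape[0]):
        fd = _slice_fd(q.data[k], q.mask[k], q.n_bins, scales)
        if fd is not None:
            fds.append(fd)
    if not fds:
        flags["fractal_fd_mean"] = flags["fractal_fd_sd"] = "no slice large enough"
        return float("nan"), float("nan"), flags
    fd_mean = float(np.mean(fds))
    if len(fds) < 2:
        flags["fractal_fd_sd"] = "single contributing slice"
        return fd_mean, 0.0, flags
    return fd_mean, float(np.std(fds, ddof=1)), flags


# ----------------------------------------------------------------- lacunarity


def _box_sums_2d(a: np.ndarray, r: int) -> np.ndarray:
    """Sums of all r x r gliding boxes via an integral image."""
    c = np.pad(a, ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    return c[r:, r:] - c[:-r, r:] - c[r:, :-r] + c[:-r, :-r]


def lacunarity(q: QuantizedVolume, box_sizes=DEFAULT_LACUNARITY_BOXES) -> float:
    """Gliding-box intensity lacunarity, mean over ``box_sizes``.

    Box mass is the sum of quantized gray levels; boxes containing any
    out-of-mask voxel are excluded.
    """
    q_masked = np.where(q.mask, q.data, 0).astype(float)
    per_r = []
    for r in box_sizes:
        masses = []
        for k in range(q.shape[0]):
            if not q.mask[k].any():
                continue
            if r > min(q.shape[1], q.shape[2]):
                continue
            sums = _box_sums_2d(q_masked[k], r)
            counts = _box_sums_2d(q.mask[k].astype(float), r)
            valid = np.isclose(counts, r * r)
            if valid.any():
                masses.append(sums[valid])
        if masses:
            m = np.concatenate(masses)
            per_r.append(1.0 + m.var() / m.mean() ** 2)
    if not per_r:
        raise EmptyMaskError("no fully in-mask gliding boxes at any requested size")
    return float(np.mean(per_r))


# -------------------------------------------------------------------- Hurst


def expected_rescaled_range(n: int) -> float:
    """Anis-Lloyd expectation of R/S for i.i.d. data, with Peters' correction."""
    i = np.arange(1, n)
    s = np.sqrt((n - i) / i).sum()
    if n <= 340:
        front = np.exp(gammaln((n - 1) / 2) - gammaln(n / 2)) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2)
    return float((n - 0.5) / n * front * s)


def _rescaled_range(x: np.ndarray) -> float | None:
    s = x.std()
    if s == 0:
        return None
    c = np.cumsum(x - x.mean())
    return float((c.max() - c.min()) / s)


def mask_profiles(q: QuantizedVolume, min_len: int = MIN_PROFILE_LEN) -> list[np.ndarray]:
    """Maximal contiguous in-mask gray-level profiles along rows and columns."""
    profiles = []
    for k in range(q.shape[0]):
        sl, msk = q.data[k], q.mask[k]
        for lines, line_masks in ((sl, msk), (sl.T, msk.T)):
            for vals, m in zip(lines, line_masks):
                if not m.any():
                    continue
                # split into contiguous runs
                breaks = np.flatnonzero(np.diff(m.astype(int)))
                for seg in np.split(np.arange(len(m)), breaks + 1):
                    if m[seg[0]] and len(seg) >= min_len:
                        profiles.append(vals[seg].astype(float))
    return profiles


def hurst_exponent(q: QuantizedVolume, min_window: int = MIN_PROFILE_LEN) -> tuple[float, dict]:
    """Bias-corrected pooled R/S Hurst estimate over in-mask profiles.

    For each dyadic window size w the log ratio of the observed R/S to its
    i.i.d. expectation is pooled over all non-overlapping segments of all
    profiles; the regression slope of that pooled ratio against log w,
    plus 0.5, is the Hurst estimate (0.5 for uncorrelated data by
    construction of the correction).
    """
    flags: dict[str, str] = {}
    profiles = mask_profiles(q, min_len=min_window)
    if not profiles:
        flags["fractal_hurst"] = f"no in-mask profile of length >= {min_window}"
        return float("nan"), flags
    max_len = max(len(p) for p in profiles)
    windows = []
    w = min_window
    while w <= max_len:
        windows.append(w)
        w *= 2
    log_w, log_ratio = [], []
    for w in windows:
        ratios = []
        e_rs = expected_rescaled_range(w)
        for p in profiles:
            for start in range(0, (len(p) // w) * w, w):
                rs = _rescaled_range(p[start : start + w])
                if rs is not None and rs > 0:
                    ratios.append(np.log(rs / e_rs))
        if ratios:
            log_w.append(np.log(w))
            log_ratio.append(np.mean(ratios))
    if len(log_w) < 2:
        flags["fractal_hurst"] = "fewer than two usable window sizes"
        return float("nan"), flags
    slope = np.polyfit(log_w, log_ratio, 1)[0]
    return float(0.5 + slope), flags


def fractal_features(q: QuantizedVolume) -> FractalFeatures:
    fd_mean, fd_sd, flags = boxcount_fd(q)
    values = {"fractal_fd_mean": fd_mean, "fractal_fd_sd": fd_sd}
    try:
        values["fractal_lacunarity"] = lacunarity(q)
    except EmptyMaskError as exc:
        values["fractal_lacunarity"] = float("nan")
        flags["fractal_lacunarity"] = str(exc)
    hurst, hflags = hurst_exponent(q)
    values["fractal_hurst"] = hurst
    flags.update(hflags)
    return FractalFeatures(values=values, flags=flags)
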