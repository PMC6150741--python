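"""Independent brute-force reference implementations.

Every function here recomputes a texture matrix or statistic by explicit
loops over voxels (no vectorization, no shared code with the package), so
the package's optimized paths can be checked cell-for-cell against them.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def oracle_glcm(data: np.ndarray, mask: np.ndarray, n_bins: int, directions, distance: int = 1):
    """Symmetric normalized GLCM by exhaustive pair enumeration."""
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    nz, ny, nx = data.shape
    for d in directions:
        dz, dy, dx = (distance * c for c in d)
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    z2, y2, x2 = z + dz, y + dy, x + dx
                    if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                        continue
                    if mask[z, y, x] and mask[z2, y2, x2]:
                        counts[data[z, y, x] - 1, data[z2, y2, x2] - 1] += 1
    counts = counts + counts.T
    return counts / counts.sum()


def oracle_gldm(data: np.ndarray, mask: np.ndarray, n_bins: int, directions, distance: int = 1):
    """Absolute gray-difference distribution by exhaustive pair enumeration."""
    counts = np.zeros(n_bins, dtype=np.int64)
    nz, ny, nx = data.shape
    for d in directions:
        dz, dy, dx = (distance * c for c in d)
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    z2, y2, x2 = z + dz, y + dy, x + dx
                    if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                        continue
                    if mask[z, y, x] and mask[z2, y2, x2]:
                        counts[abs(int(data[z, y, x]) - int(data[z2, y2, x2]))] += 1
    return counts / counts.sum()


def _neighbors(shape, z, y, x, offsets):
    for dz, dy, dx in offsets:
        z2, y2, x2 = z + dz, y + dy, x + dx
        if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2]:
            yield z2, y2, x2


def _offsets_26():
    return [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]


def oracle_ngtdm(data: np.ndarray, mask: np.ndarray, n_bins: int):
    """NGTDM s(g), p(g), n_valid by per-voxel neighborhood enumeration (26-nbhd)."""
    offsets = _offsets_26()
    s = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    n_valid = 0
    nz, ny, nx = data.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                nbr = [
                    float(data[p]) for p in _neighbors(data.shape, z, y, x, offsets) if mask[p]
                ]
                if not nbr:
                    continue
                n_valid += 1
                g = int(data[z, y, x])
                counts[g - 1] += 1
                s[g - 1] += abs(g - sum(nbr) / len(nbr))
    return s, counts / n_valid, n_valid


def oracle_glrlm(data: np.ndarray, mask: np.ndarray, n_bins: int, directions):
    """Run-length counts by walking every line in every direction."""
    nz, ny, nx = data.shape
    max_len = max(data.shape)
    r = np.zeros((n_bins, max_len), dtype=np.int64)
    for d in directions:
        dz, dy, dx = d
        visited = np.zeros(data.shape, dtype=bool)
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    # only start walking from the beginning of each lattice line
                    zp, yp, xp = z - dz, y - dy, x - dx
                    if 0 <= zp < nz and 0 <= yp < ny and 0 <= xp < nx:
                        continue
                    # walk the line, splitting into maximal in-mask same-level runs
                    run_level, run_len = None, 0
                    cz, cy, cx = z, y, x
                    while 0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx:
                        if mask[cz, cy, cx]:
                            g = int(data[cz, cy, cx])
                            if g == run_level:
                                run_len += 1
                            else:
                                if run_level is not None:
                                    r[run_level - 1, run_len - 1] += 1
                                run_level, run_len = g, 1
                        else:
                            if run_level is not None:
                                r[run_level - 1, run_len - 1] += 1
                            run_level, run_len = None, 0
                        visited[cz, cy, cx] = True
                        cz, cy, cx = cz + dz, cy + dy, cx + dx
                    if run_level is not None:
                        r[run_level - 1, run_len - 1] += 1
        assert visited.all()
    return r


def oracle_glzsm(data: np.ndarray, mask: np.ndarray):
    """Zone (gray, size) list by breadth-first flood fill, 26-connectivity."""
    offsets = _offsets_26()
    seen = np.zeros(data.shape, dtype=bool)
    zones = []
    nz, ny, nx = data.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                g = int(data[z, y, x])
                size = 0
                queue = deque([(z, y, x)])
                seen[z, y, x] = True
                while queue:
                    cur = queue.popleft()
                    size += 1
                    for p in _neighbors(data.shape, *cur, offsets):
                        if mask[p] and not seen[p] and int(data[p]) == g:
                            seen[p] = True
                            queue.append(p)
                zones.append((g, size))
    return sorted(zones)


def oracle_bin(x: float, bin_edges: np.ndarray) -> int:
    """Bin assignment by binary search over edges (top bin right-closed)."""
    n_bins = len(bin_edges) - 1
    if x >= bin_edges[-1]:
        return n_bins
    if x <= bin_edges[0]:
        return 1
    lo, hi = 0, n_bins
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if x >= bin_edges[mid]:
            lo = mid
        else:
            hi = mid
    return lo + 1


def oracle_lacunarity_2d(values: np.ndarray, mask: np.ndarray, r: int) -> float:
    """Gliding-box lacunarity of one slice by explicit box enumeration."""
    ny, nx = values.shape
    masses = []
    for y in range(ny - r + 1):
        for x in range(nx - r + 1):
            box_mask = mask[y : y + r, x : x + r]
            if box_mask.all():
                masses.append(values[y : y + r, x : x + r].sum())
    m = np.asarray(masses, dtype=float)
    return 1.0 + m.var() / m.mean() ** 2


def oracle_glcm_features(p: np.ndarray) -> dict:
    """GLCM feature panel by explicit double loops over matrix cells."""
    g = p.shape[0]
    import math

    ent = eng = con = hom = idm = dis = 0.0
    mu = 0.0
    for i in range(1, g + 1):
        for j in range(1, g + 1):
            pij = p[i - 1, j - 1]
            if pij > 0:
                ent -= pij * math.log2(pij)
            eng += pij * pij
            con += pij * (i - j) ** 2
            hom += pij / (1 + abs(i - j))
            idm += pij / (1 + (i - j) ** 2)
            dis += pij * abs(i - j)
            mu += i * pij  # row marginal mean (symmetric matrix)
    var = 0.0
    for i in range(1, g + 1):
        var += (i - mu) ** 2 * sum(p[i - 1, j - 1] for j in range(g))
    corr = shade = prom = 0.0
    for i in range(1, g + 1):
        for j in range(1, g + 1):
            pij = p[i - 1, j - 1]
            if var > 0:
                corr += (i - mu) * (j - mu) * pij / var
            shade += pij * ((i - mu) + (j - mu)) ** 3
            prom += pij * ((i - mu) + (j - mu)) ** 4
    p_sum = {}
    p_diff = {}
    for i in range(1, g + 1):
        for j in range(1, g + 1):
            p_sum[i + j] = p_sum.get(i + j, 0.0) + p[i - 1, j - 1]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p[i - 1, j - 1]
    sum_ent = -sum(v * math.log2(v) for v in p_sum.values() if v > 0)
    diff_ent = -sum(v * math.log2(v) for v in p_diff.values() if v > 0)
    sum_avg = sum(k * v for k, v in p_sum.items())
    return {
        "glcm_entropy": ent,
        "glcm_energy": eng,
        "glcm_contrast": con,
        "glcm_homogeneity": hom,
        "glcm_idm": idm,
        "glcm_dissimilarity": dis,
        "glcm_correlation": corr,
        "glcm_cluster_shade": shade,
        "glcm_cluster_prominence": prom,
        "glcm_sum_entropy": sum_ent,
        "glcm_difference_entropy": diff_ent,
        "glcm_sum_average": sum_avg,
    }


def oracle_glrlm_features(r: np.ndarray, n_voxels: int, n_directions: int) -> dict:
    """Run-length feature panel by explicit loops over matrix cells."""
    g_max, l_max = r.shape
    nr = float(r.sum())
    sre = lre = lgre = hgre = 0.0
    for g in range(1, g_max + 1):
        for l in range(1, l_max + 1):
            c = float(r[g - 1, l - 1])
            sre += c / l**2
            lre += c * l**2
            lgre += c / g**2
            hgre += c * g**2
    gln = sum(float(r[g - 1, :].sum()) ** 2 for g in range(1, g_max + 1))
    rln = sum(float(r[:, l - 1].sum()) ** 2 for l in range(1, l_max + 1))
    return {
        "glrl_sre": sre / nr,
        "glrl_lre": lre / nr,
        "glrl_intensity_variability": gln / nr,
        "glrl_run_length_variability": rln / nr,
        "glrl_run_percentage": nr / (n_voxels * n_directions),
        "glrl_low_gray_run_emphasis": lgre / nr,
        "glrl_high_gray_run_emphasis": hgre / nr,
    }


def oracle_glzsm_features(zones: list, n_voxels: int) -> dict:
    """Zone-size feature panel by explicit loops over the zone list."""
    nz = float(len(zones))
    grays = [g for g, _ in zones]
    sizes = [s for _, s in zones]
    sze = sum(1.0 / s**2 for s in sizes) / nz
    lze = sum(float(s) ** 2 for s in sizes) / nz
    lgze = sum(1.0 / g**2 for g in grays) / nz
    hgze = sum(float(g) ** 2 for g in grays) / nz
    gln = sum(grays.count(g) ** 2 for g in set(grays)) / nz
    zsn = sum(sizes.count(s) ** 2 for s in set(sizes)) / nz
    g_mean = sum(grays) / nz
    s_mean = sum(sizes) / nz
    return {
        "glzsm_short_zone_emphasis": sze,
        "glzsm_large_zone_emphasis": lze,
        "glzsm_intensity_nonuniformity": gln,
        "glzsm_intensity_variability": sum((g - g_mean) ** 2 for g in grays) / nz,
        "glzsm_size_zone_variability": zsn,
        "glzsm_zone_percentage": nz / n_voxels,
        "glzsm_low_gray_zone_emphasis": lgze,
        "glzsm_high_gray_zone_emphasis": hgze,
        "glzsm_size_variance": sum((s - s_mean) ** 2 for s in sizes) / nz,
    }


def oracle_ngtdm_features(s: np.ndarray, p: np.ndarray, n_valid: int, eps: float = 1e-12) -> dict:
    """NGTDM feature panel by explicit loops over gray levels."""
    levels = [i + 1 for i in range(len(p)) if p[i] > 0]
    ps = sum(p[g - 1] * s[g - 1] for g in levels)
    coarseness = min(1.0 / (eps + ps), 1.0 / eps)
    ng = len(levels)
    if ng > 1:
        acc = 0.0
        for gi in levels:
            for gj in levels:
                acc += p[gi - 1] * p[gj - 1] * (gi - gj) ** 2
        contrast = acc / (ng * (ng - 1)) * float(np.sum(s)) / n_valid
    else:
        contrast = 0.0
    den = sum(
        abs(gi * p[gi - 1] - gj * p[gj - 1]) for gi in levels for gj in levels
    )
    busyness = ps / den if den > 0 else 0.0
    comp = 0.0
    for gi in levels:
        for gj in levels:
            comp += (
                abs(gi - gj)
                * (p[gi - 1] * s[gi - 1] + p[gj - 1] * s[gj - 1])
                / (n_valid * (p[gi - 1] + p[gj - 1]))
            )
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": comp,
    }
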