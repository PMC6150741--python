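"""Global first-order (histogram) features of the quantized tumor volume.

These summarize the in-mask gray-level distribution without any spatial
information.  Location/scale moments (mean, median, SD) are reported on the
original intensity scale via the quantization bin centers, so they track
genuine signal change between repeat studies; shape moments
(skewness, excess kurtosis — Fisher convention, n denominators), entropy
(bits) and energy (uniformity) are computed from the bin occupancy
probabilities and are invariant to affine intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..errors import EmptyMaskError
from ..volume import QuantizedVolume

HISTOGRAM_FEATURES = (
    "hist_mean",
    "hist_median",
    "hist_sd",
    "hist_skewness",
    "hist_kurtosis",
    "hist_entropy",
    "hist_energy",
)


@dataclass
class HistogramFeatures:
    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)


def bin_probabilities(q: QuantizedVolume) -> np.ndarray:
    """Occupancy probability of each gray bin over in-mask voxels."""
    vals = q.masked_values()
    if vals.size == 0:
        raise EmptyMaskError("no in-mask voxels")
    counts = np.bincount(vals, minlength=q.n_bins + 1)[1:]
    return counts / counts.sum()


def histogram_features(q: QuantizedVolume) -> HistogramFeatures:
    vals = q.masked_values()
    if vals.size == 0:
        raise EmptyMaskError("no in-mask voxels")
    flags: dict[str, str] = {}
    x = q.bin_centers[vals - 1]
    p = bin_probabilities(q)
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((p**2).sum())
    sd = float(x.std())  # population (n) denominator
    if sd == 0 or vals.size < 2:
        skew = kurt = 0.0
        flags["hist_skewness"] = flags["hist_kurtosis"] = "undefined for constant input"
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return HistogramFeatures(
        values={
            "hist_mean": float(x.mean()),
            "hist_median": float(np.median(x)),
            "hist_sd": sd,
            "hist_skewness": skew,
            "hist_kurtosis": kurt,
            "hist_entropy": entropy,
            "hist_energy": energy,
        },
        flags=flags,
    )
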