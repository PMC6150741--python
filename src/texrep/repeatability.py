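"""Test-retest repeatability statistics.

For each feature measured twice per subject (day 1 vs day 2), this module
computes the Bland-Altman mean difference and 95% limits of agreement with
confidence intervals on the limits, the within-subject coefficient of
variation (wCV), the repeatability coefficient, and a reliability class.

With differences d_i = x1_i - x2_i over n subjects:

* limits of agreement:  mean(d) +/- 1.96 * SD(d)   (sample SD, n-1),
  each limit carrying a 95% CI of half-width t_{0.975,n-1} * sqrt(3 s^2 / n)
* within-subject SD:    s_w = sqrt(sum d^2 / (2n))
* wCV (percent):        100 * s_w / mean of all 2n pooled measurements
* repeatability coeff.: r = 1.96 * sqrt(sum d^2 / n) = 1.96 * sqrt(2) * s_w
  (in 95% of cases the difference between two repeat measurements of the
  same subject is below r)

Reliability bands on wCV: <=10% good, (10,15]% acceptable, (15,30)%
intermediate, [30,50)% moderate-poor, >=50% unreliable (boundary 50%
assigned to unreliable, boundary 10% to good).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

RELIABILITY_CLASSES = ("good", "acceptable", "intermediate", "moderate-poor", "unreliable")


@dataclass
class RepeatabilityRecord:
    feature_name: str
    n: int
    mean_difference: float
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    wcv_pct: float
    repeatability_coefficient: float
    reliability_class: str
    flags: dict[str, str] = field(default_factory=dict)


def _as_pair_arrays(x1, x2) -> tuple[np.ndarray, np.ndarray]:
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be 1D arrays of equal length")
    return x1, x2


def bland_altman(x1, x2) -> tuple[float, float, float, tuple[float, float], tuple[float, float]]:
    """Mean difference, 95% limits of agreement, and CIs on each limit."""
    x1, x2 = _as_pair_arrays(x1, x2)
    n = len(x1)
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got {n}")
    d = x1 - x2
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    lower = mean_d - 1.96 * sd
    upper = mean_d + 1.96 * sd
    half = float(stats.t.ppf(0.975, n - 1) * np.sqrt(3 * sd**2 / n))
    return mean_d, lower, upper, (lower - half, lower + half), (upper - half, upper + half)


def within_subject_sd(x1, x2) -> float:
    x1, x2 = _as_pair_arrays(x1, x2)
    d = x1 - x2
    return float(np.sqrt((d**2).sum() / (2 * len(d))))


def wcv(x1, x2) -> tuple[float, dict[str, str]]:
    """Within-subject coefficient of variation in percent, with flags.

    The denominator is the mean of all 2n pooled measurements. A zero or
    sign-mixed scale makes a CV uninterpretable; such cases are flagged and
    should be excluded from reliability classification.
    """
    x1, x2 = _as_pair_arrays(x1, x2)
    if len(x1) < 2:
        raise ValueError("need at least 2 subjects")
    flags: dict[str, str] = {}
    pooled = np.concatenate([x1, x2])
    group_mean = float(pooled.mean())
    if group_mean == 0:
        return float("nan"), {"wcv": "not interpretable: zero group mean"}
    if pooled.min() < 0 < pooled.max():
        flags["wcv"] = "not interpretable: sign-mixed feature values"
    value = 100.0 * within_subject_sd(x1, x2) / abs(group_mean)
    return value, flags


def repeatability_coefficient(x1, x2) -> float:
    """1.96 * sqrt(sum d^2 / n): the 95% bound on a repeat-measurement change."""
    x1, x2 = _as_pair_arrays(x1, x2)
    d = x1 - x2
    return float(1.96 * np.sqrt((d**2).sum() / len(d)))


def classify_reliability(wcv_pct: float) -> str:
    if not np.isfinite(wcv_pct):
        return "not-interpretable"
    if wcv_pct < 0:
        raise ValueError(f"wCV must be >= 0, got {wcv_pct}")
    if wcv_pct <= 10:
        return "good"
    if wcv_pct <= 15:
        return "acceptable"
    if wcv_pct < 30:
        return "intermediate"
    if wcv_pct < 50:
        return "moderate-poor"
    return "unreliable"


def repeatability_record(feature_name: str, x1, x2) -> RepeatabilityRecord:
    mean_d, lo, hi, lo_ci, hi_ci = bland_altman(x1, x2)
    wcv_pct, flags = wcv(x1, x2)
    rc = repeatability_coefficient(x1, x2)
    cls = "not-interpretable" if "wcv" in flags else classify_reliability(wcv_pct)
    return RepeatabilityRecord(
        feature_name=feature_name,
        n=len(np.asarray(x1)),
        mean_difference=mean_d,
        loa_lower=lo,
        loa_upper=hi,
        loa_lower_ci=lo_ci,
        loa_upper_ci=hi_ci,
        wcv_pct=wcv_pct,
        repeatability_coefficient=rc,
        reliability_class=cls,
        flags=flags,
    )


def summarize_repeatability(features_long: pd.DataFrame) -> pd.DataFrame:
    """Per-reader, per-feature repeatability table from long-format features.

    Expects columns ``subject_id, reader_id, day, feature_name, value`` with
    exactly two days per subject and reader.  Returns one row per
    (reader_id, feature_name).
    """
    required = {"subject_id", "reader_id", "day", "feature_name", "value"}
    missing = required - set(features_long.columns)
    if missing:
        raise ValueError(f"features table missing columns: {sorted(missing)}")
    rows = []
    for (reader, feature), grp in features_long.groupby(["reader_id", "feature_name"], sort=False):
        wide = grp.pivot_table(index="subject_id", columns="day", values="value")
        if not {1, 2}.issubset(wide.columns):
            raise ValueError(f"feature {feature!r} reader {reader!r} lacks paired days")
        wide = wide.dropna(subset=[1, 2])
        rec = repeatability_record(feature, wide[1].to_numpy(), wide[2].to_numpy())
        rows.append(
            {
                "reader_id": reader,
                "feature_name": feature,
                "n": rec.n,
                "mean_difference": rec.mean_difference,
                "loa_lower": rec.loa_lower,
                "loa_upper": rec.loa_upper,
                "loa_lower_ci_low": rec.loa_lower_ci[0],
                "loa_lower_ci_high": rec.loa_lower_ci[1],
                "loa_upper_ci_low": rec.loa_upper_ci[0],
                "loa_upper_ci_high": rec.loa_upper_ci[1],
                "wcv_pct": rec.wcv_pct,
                "repeatability_coefficient": rec.repeatability_coefficient,
                "reliability_class": rec.reliability_class,
                "flags": "; ".join(f"{k}: {v}" for k, v in rec.flags.items()),
            }
        )
    return pd.DataFrame(rows)
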