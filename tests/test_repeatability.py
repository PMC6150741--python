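"""Bland-Altman, wCV, repeatability coefficient and reliability bands."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from texrep.repeatability import (
    bland_altman,
    classify_reliability,
    repeatability_coefficient,
    repeatability_record,
    summarize_repeatability,
    wcv,
    within_subject_sd,
)


class TestBlandAltman:
    def test_all_zero_differences(self):
        mean_d, lo, hi, _, _ = bland_altman([3.0, 4.0], [3.0, 4.0])
        assert (mean_d, lo, hi) == (0.0, 0.0, 0.0)

    def test_two_subject_hand_values(self):
        # d = (-2, +2): SD = 2.8284, LoA = +/- 5.544
        mean_d, lo, hi, _, _ = bland_altman([10.0, 20.0], [12.0, 18.0])
        assert mean_d == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(8.0), abs=1e-10)
        assert hi == pytest.approx(5.544, abs=1e-3)
        assert lo == pytest.approx(-hi)

    def test_translation_equivariance(self, rng):
        x1 = rng.normal(50, 5, size=12)
        x2 = rng.normal(50, 5, size=12)
        c = 7.3
        base = bland_altman(x1, x2)
        shifted = bland_altman(x1 + c, x2)
        for a, b in zip(base[:3], shifted[:3]):
            assert b == pytest.approx(a + c, abs=1e-10)

    def test_limits_bracket_mean_difference(self, rng):
        x1 = rng.normal(10, 2, size=9)
        x2 = rng.normal(10, 2, size=9)
        mean_d, lo, hi, lo_ci, hi_ci = bland_altman(x1, x2)
        assert lo <= mean_d <= hi
        assert lo_ci[0] < lo < lo_ci[1]
        assert hi_ci[0] < hi < hi_ci[1]

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestWCV:
    def test_hand_values(self):
        # x1=(10,20), x2=(12,18): s_w = sqrt(8/4) = 1.4142, mean 15
        value, flags = wcv([10.0, 20.0], [12.0, 18.0])
        assert value == pytest.approx(100 * np.sqrt(2) / 15, abs=1e-10)
        assert value == pytest.approx(9.428, abs=1e-3)
        assert not flags

    def test_identical_measurements_give_zero(self):
        value, _ = wcv([5.0, 8.0, 13.0], [5.0, 8.0, 13.0])
        assert value == 0.0

    def test_scale_invariance(self, rng):
        x1 = rng.normal(100, 10, size=10)
        x2 = x1 * rng.normal(1, 0.05, size=10)
        v1, _ = wcv(x1, x2)
        v2, _ = wcv(3.7 * x1, 3.7 * x2)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_sign_mixed_values_flagged(self):
        _, flags = wcv([-1.0, 2.0], [1.0, 2.5])
        assert "wcv" in flags


class TestRepeatabilityCoefficient:
    def test_hand_value(self):
        assert repeatability_coefficient([10.0, 20.0], [12.0, 18.0]) == pytest.approx(3.92)

    def test_zero_differences(self):
        assert repeatability_coefficient([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_identity_with_within_subject_sd(self, rng):
        x1 = rng.normal(10, 3, size=20)
        x2 = rng.normal(10, 3, size=20)
        r = repeatability_coefficient(x1, x2)
        assert r == pytest.approx(1.96 * np.sqrt(2) * within_subject_sd(x1, x2), abs=1e-12)

    def test_monte_carlo_95th_percentile_coverage(self):
        # empirical 95th percentile of |d| for Gaussian d matches r within 2%
        rng = np.random.default_rng(12345)
        d = rng.normal(0, 2.5, size=100_000)
        r = repeatability_coefficient(d, np.zeros_like(d))
        q95 = np.quantile(np.abs(d), 0.95)
        assert q95 == pytest.approx(r, rel=0.02)


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, "good"),
            (9.43, "good"),
            (10.0, "good"),
            (12.0, "acceptable"),
            (15.0, "acceptable"),
            (20.0, "intermediate"),
            (30.0, "moderate-poor"),
            (49.9, "moderate-poor"),
            (50.0, "unreliable"),
            (80.0, "unreliable"),
        ],
    )
    def test_band_boundaries(self, value, expected):
        assert classify_reliability(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_reliability(-1.0)


class TestInvariances:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**16))
    def test_subject_permutation_leaves_statistics_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(20, 4, size=10)
        x2 = x1 * rng.normal(1, 0.08, size=10)
        perm = rng.permutation(10)
        a = repeatability_record("f", x1, x2)
        b = repeatability_record("f", x1[perm], x2[perm])
        assert a.mean_difference == pytest.approx(b.mean_difference, abs=1e-12)
        assert a.loa_lower == pytest.approx(b.loa_lower, abs=1e-12)
        assert a.wcv_pct == pytest.approx(b.wcv_pct, abs=1e-12)
        assert a.repeatability_coefficient == pytest.approx(b.repeatability_coefficient, abs=1e-12)

    @pytest.mark.parametrize("n", [50, 200])
    def test_multiplicative_noise_cv_recovery(self, n):
        # x_ij = mu_i (1 + e_ij), e ~ N(0, c): wCV estimate ~ 100c within 3 SE
        c = 0.10
        rng = np.random.default_rng(n)
        mu = rng.uniform(80, 120, size=n)
        x1 = mu * (1 + rng.normal(0, c, size=n))
        x2 = mu * (1 + rng.normal(0, c, size=n))
        value, _ = wcv(x1, x2)
        se = 100 * c / np.sqrt(2 * n)
        assert abs(value - 100 * c) < 3 * se


def test_summarize_repeatability_long_format():
    import pandas as pd

    rows = []
    for s, (a, b) in enumerate([(10, 12), (20, 18), (15, 15)]):
        rows.append(dict(subject_id=f"s{s}", reader_id=1, day=1, feature_name="f1", value=a))
        rows.append(dict(subject_id=f"s{s}", reader_id=1, day=2, feature_name="f1", value=b))
    out = summarize_repeatability(pd.DataFrame(rows))
    assert len(out) == 1
    row = out.iloc[0]
    assert row["n"] == 3
    assert row["reliability_class"] in ("good", "acceptable")
    assert row["loa_lower"] <= row["mean_difference"] <= row["loa_upper"]
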