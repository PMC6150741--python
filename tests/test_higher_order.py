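"""NGTDM / GLRLM / GLZSM: hand examples, mass conservation, oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_quantized, random_quantized
from oracles import (
    oracle_glrlm,
    oracle_glrlm_features,
    oracle_glzsm,
    oracle_glzsm_features,
    oracle_ngtdm,
    oracle_ngtdm_features,
)
from texrep.features.higher_order import (
    RUN_DIRECTIONS_3D,
    compute_glrlm,
    compute_glzsm,
    compute_ngtdm,
    glrlm_features,
    glzsm_features,
    ngtdm_features,
)


class TestNGTDM:
    def test_constant_volume_zero_contrast_capped_coarseness(self):
        m = compute_ngtdm(make_quantized(np.full((2, 4, 4), 3), n_bins=4))
        out = ngtdm_features(m)
        assert out.values["ngtdm_contrast"] == 0.0
        assert out.values["ngtdm_coarseness"] == pytest.approx(1e12)
        assert "ngtdm_busyness" in out.flags

    def test_fixed_pattern_matches_neighborhood_enumeration(self):
        pattern = np.array([[[1, 2, 1, 2], [2, 1, 2, 1], [1, 1, 2, 2], [2, 2, 1, 1]]])
        q = make_quantized(pattern, n_bins=2)
        m = compute_ngtdm(q)
        s, p, n_valid = oracle_ngtdm(q.data, q.mask, 2)
        np.testing.assert_allclose(m.s, s, atol=1e-12)
        np.testing.assert_allclose(m.p, p, atol=1e-12)
        assert m.n_valid == n_valid
        got = ngtdm_features(m).values
        expected = oracle_ngtdm_features(s, p, n_valid)
        for name, val in expected.items():
            assert got[name] == pytest.approx(val, rel=1e-10), name

    def test_checkerboard_busier_than_split(self):
        yy, xx = np.mgrid[0:8, 0:8]
        board = 1 + (yy + xx) % 2
        split = np.ones((8, 8), int)
        split[:, 4:] = 2
        f_board = ngtdm_features(compute_ngtdm(make_quantized(board[None], n_bins=2))).values
        f_split = ngtdm_features(compute_ngtdm(make_quantized(split[None], n_bins=2))).values
        assert f_board["ngtdm_contrast"] > f_split["ngtdm_contrast"]


class TestGLRLM:
    def test_single_row_hand_enumeration(self):
        q = make_quantized([[[1, 1, 2, 2, 2]]], n_bins=2)
        m = compute_glrlm(q, directions=((0, 0, 1),))
        f = glrlm_features(m).values
        assert f["glrl_sre"] == pytest.approx(0.5 * (1 / 4 + 1 / 9))
        assert f["glrl_intensity_variability"] == pytest.approx(1.0)
        assert f["glrl_run_length_variability"] == pytest.approx(1.0)
        assert f["glrl_run_percentage"] == pytest.approx(2 / 5)

    @pytest.mark.parametrize("length", [3, 7])
    def test_constant_row_closed_form(self, length):
        q = make_quantized(np.ones((1, 1, length), int), n_bins=2)
        f = glrlm_features(compute_glrlm(q, directions=((0, 0, 1),))).values
        assert f["glrl_sre"] == pytest.approx(1 / length**2)
        assert f["glrl_lre"] == pytest.approx(length**2)
        assert f["glrl_run_percentage"] == pytest.approx(1 / length)

    def test_run_percentage_grows_with_gray_levels(self, rng):
        rps = []
        for n_bins in (2, 4, 16):
            data = rng.integers(1, n_bins + 1, size=(3, 12, 12))
            f = glrlm_features(compute_glrlm(make_quantized(data, n_bins=n_bins))).values
            rps.append(f["glrl_run_percentage"])
        assert rps[0] < rps[1] < rps[2]

    def test_mass_conservation_and_oracle(self, rng):
        for _ in range(5):
            q, mask = random_quantized(rng, (3, 5, 5), 3, p_mask=0.8)
            m = compute_glrlm(q)
            oracle = oracle_glrlm(q.data, q.mask, 3, RUN_DIRECTIONS_3D)
            assert np.array_equal(m.r, oracle)
            lengths = np.arange(1, m.r.shape[1] + 1)
            assert (m.r * lengths).sum() == q.mask.sum() * 13


class TestGLZSM:
    def test_2x2_hand_enumeration(self):
        q = make_quantized([[[1, 1], [1, 2]]], n_bins=2)
        m = compute_glzsm(q)
        f = glzsm_features(m).values
        assert f["glzsm_short_zone_emphasis"] == pytest.approx(0.5 * (1 / 9 + 1))
        assert f["glzsm_intensity_nonuniformity"] == pytest.approx(1.0)
        assert f["glzsm_size_zone_variability"] == pytest.approx(1.0)
        assert f["glzsm_zone_percentage"] == pytest.approx(0.5)

    def test_constant_volume_single_zone_closed_form(self):
        q = make_quantized(np.full((2, 3, 3), 2), n_bins=4)
        f = glzsm_features(compute_glzsm(q)).values
        np_vox = 18
        assert f["glzsm_zone_percentage"] == pytest.approx(1 / np_vox)
        assert f["glzsm_large_zone_emphasis"] == pytest.approx(np_vox**2)

    def test_checkerboard_6conn_all_singleton_zones(self):
        zz, yy, xx = np.mgrid[0:4, 0:4, 0:4]
        board = 1 + (zz + yy + xx) % 2
        f = glzsm_features(compute_glzsm(make_quantized(board, n_bins=2), connectivity=6)).values
        assert f["glzsm_short_zone_emphasis"] == pytest.approx(1.0)

    def test_zone_list_and_features_match_flood_fill(self, rng):
        for _ in range(5):
            q, mask = random_quantized(rng, (3, 5, 5), 3, p_mask=0.8)
            m = compute_glzsm(q)
            got = sorted(zip(m.zone_gray.tolist(), m.zone_size.tolist()))
            expected = oracle_glzsm(q.data, q.mask)
            assert got == expected
            assert m.zone_size.sum() == q.mask.sum()
            got_f = glzsm_features(m).values
            expected_f = oracle_glzsm_features(expected, int(q.mask.sum()))
            for name, val in expected_f.items():
                assert got_f[name] == pytest.approx(val, rel=1e-10), name

    def test_features_invariant_to_translation_in_larger_grid(self, rng):
        data = rng.integers(1, 4, size=(2, 4, 4))
        small = make_quantized(data, n_bins=3)
        big_data = np.zeros((4, 8, 8), int)
        big_data[1:3, 2:6, 3:7] = data
        big = make_quantized(big_data, n_bins=3, mask=big_data > 0)
        for compute, feats in (
            (compute_glzsm, glzsm_features),
            (compute_glrlm, glrlm_features),
            (compute_ngtdm, ngtdm_features),
        ):
            f1 = feats(compute(small)).values
            f2 = feats(compute(big)).values
            for name in f1:
                assert f1[name] == pytest.approx(f2[name], rel=1e-10), name


def test_coarseness_increases_with_correlation_length():
    """Smoother phantoms have longer runs and larger zones (monotone medians)."""
    from texrep.preprocessing import quantize
    from texrep.synthetic import PhantomSpec, generate_phantom

    medians = {}
    for cl in (1.0, 8.0):
        lre, lze = [], []
        for seed in range(8):
            spec = PhantomSpec(
                shape=(48, 48, 6),
                voxel_size=(1.0, 1.0, 4.0),
                correlation_length=cl,
                tumor_axes=(16.0, 16.0, 8.0),
                boundary_irregularity=0.0,
                seed=seed,
            )
            vol, mask = generate_phantom(spec)
            q = quantize(vol, mask, 16)
            lre.append(glrlm_features(compute_glrlm(q)).values["glrl_lre"])
            lze.append(glzsm_features(compute_glzsm(q)).values["glzsm_large_zone_emphasis"])
        medians[cl] = (np.median(lre), np.median(lze))
    assert medians[8.0][0] > medians[1.0][0]
    assert medians[8.0][1] > medians[1.0][1]
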