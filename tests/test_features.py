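"""The 75-feature panel: structure, worked examples, and oracle agreement."""

import numpy as np
import pytest

import oracles
from viascreen.features import (
    FAMILY_SLICES,
    FEATURE_NAMES,
    color_features,
    dwt_features,
    extract_all,
    glcm_features,
    glcm_matrices,
    glszm_features,
    glszm_matrix,
    lbp_features,
    ngtdm_features,
    quantize,
)
from viascreen.features.glcm import haralick_stats
from viascreen.features.ngtdm import COARSENESS_CAP


def _rand_raster(rng, levels=3, max_side=6):
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    gray = rng.integers(0, levels, (h, w))
    mask = rng.random((h, w)) < 0.85
    if not mask.any():
        mask[0, 0] = True
    return gray, mask


class TestPanelStructure:
    def test_exactly_75_named_features(self, demo_crop_mask):
        crop, mask = demo_crop_mask
        vec = extract_all(crop, mask)
        assert len(vec) == 75
        assert list(vec.index) == FEATURE_NAMES

    def test_family_partition_12_28_5_14_6_10(self):
        sizes = {fam: sl.stop - sl.start for fam, sl in FAMILY_SLICES.items()}
        assert sizes == {"color": 12, "glcm": 28, "ngtdm": 5, "glszm": 14, "dwt": 6, "lbp": 10}

    def test_deterministic(self, demo_crop_mask):
        crop, mask = demo_crop_mask
        assert extract_all(crop, mask).equals(extract_all(crop, mask))

    def test_no_nan_on_random_crops(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            crop = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
            mask = np.zeros((32, 32), dtype=bool)
            mask[4:28, 4:28] = rng.random((24, 24)) < 0.7
            if mask.sum() < 64:
                mask[4:28, 4:28] = True
            assert not extract_all(crop, mask).isna().any()

    def test_small_mask_rejected(self, demo_crop_mask):
        crop, _ = demo_crop_mask
        tiny = np.zeros(crop.shape[:2], dtype=bool)
        tiny[0, 0] = True
        with pytest.raises(ValueError):
            extract_all(crop, tiny)


class TestColorFeatures:
    def test_uniform_gray_with_ratio_guard(self):
        crop = np.full((10, 10, 3), 128, dtype=np.uint8)
        out = color_features(crop, np.ones((10, 10), bool))
        assert out["color_mean_R"] == out["color_mean_G"] == out["color_mean_B"] == 128
        assert all(
            out[f"color_std_{c}"] == pytest.approx(0, abs=1e-12)
            for c in ("R", "G", "B", "G_over_Rp1", "B_over_Rp1", "V")
        )
        assert out["color_mean_G_over_Rp1"] == pytest.approx(128 / 129)

    def test_ratio_example(self):
        crop = np.full((10, 10, 3), (200, 100, 50), dtype=np.uint8)
        out = color_features(crop, np.ones((10, 10), bool))
        assert out["color_mean_B_over_Rp1"] == pytest.approx(50 / 201)
        assert out["color_mean_V"] == pytest.approx(200 / 255)

    def test_masked_statistics_ignore_outside(self):
        crop = np.zeros((16, 16, 3), dtype=np.uint8)
        crop[:, :8] = 100
        mask = np.zeros((16, 16), dtype=bool)
        mask[:, :8] = True
        out = color_features(crop, mask)
        assert out["color_mean_R"] == 100 and out["color_std_R"] == 0


class TestGlcm:
    def test_constant_region_energy_one_contrast_zero(self):
        gray = np.zeros((8, 8), dtype=int)
        out = glcm_features(gray, np.ones((8, 8), bool), levels=4)
        assert out["glcm_asm_mean"] == 1.0
        assert out["glcm_contrast_mean"] == 0.0

    def test_toy_raster_pair_counts_match_enumeration(self):
        gray = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 3, 3], [2, 2, 3, 3]])
        mask = np.ones((4, 4), bool)
        mats = glcm_matrices(gray, mask, levels=4)
        for mat, angle in zip(mats, (0, 45, 90, 135)):
            assert np.allclose(mat, oracles.glcm_matrix_naive(gray, mask, 4, angle))

    def test_rotation_leaves_direction_means_invariant(self):
        rng = np.random.default_rng(2)
        gray = rng.integers(0, 4, (7, 7))
        mask = np.ones((7, 7), bool)
        a = glcm_features(gray, mask, levels=4)
        b = glcm_features(np.rot90(gray), mask, levels=4)
        for stat in ("asm", "contrast", "entropy", "idm"):
            assert a[f"glcm_{stat}_mean"] == pytest.approx(b[f"glcm_{stat}_mean"], abs=1e-12)

    def test_haralick_statistics_match_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            gray, mask = _rand_raster(rng)
            if not oracles.glcm_matrix_naive(gray, mask, 3, 0).sum():
                continue
            for mat in glcm_matrices(gray, mask, 3):
                if mat.sum() == 0:
                    continue
                ours = haralick_stats(mat)
                ref = oracles.haralick_naive(mat)
                for key, val in ref.items():
                    assert ours[key] == pytest.approx(val, abs=1e-9), key


class TestNgtdm:
    def test_constant_region_limits(self):
        gray = np.zeros((6, 6), dtype=int)
        out = ngtdm_features(gray, np.ones((6, 6), bool), levels=4)
        assert out["ngtdm_coarseness"] == COARSENESS_CAP
        assert out["ngtdm_contrast"] == 0.0

    def test_two_level_toy_matches_loop_oracle(self):
        gray = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]])
        mask = np.ones((4, 4), bool)
        ours = ngtdm_features(gray, mask, levels=2)
        ref = oracles.ngtdm_features_naive(gray, mask, levels=2)
        for key, val in ref.items():
            assert ours[key] == pytest.approx(val, abs=1e-12), key

    def test_doubling_level_gap_increases_contrast(self):
        base = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        mask = np.ones((3, 3), bool)
        low = ngtdm_features(base, mask, levels=3)["ngtdm_contrast"]
        high = ngtdm_features(base * 2, mask, levels=3)["ngtdm_contrast"]
        assert high > low


class TestGlszm:
    def test_constant_region_single_zone(self):
        gray = np.zeros((10, 10), dtype=int)
        out = glszm_features(gray, np.ones((10, 10), bool), levels=4)
        assert out["glszm_zone_percentage"] == pytest.approx(0.01)
        assert out["glszm_gray_level_variance"] == 0.0

    def test_toy_zone_matrix_matches_flood_fill(self):
        gray = np.array([[0, 0, 1], [0, 1, 1], [2, 2, 2]])
        mask = np.ones((3, 3), bool)
        assert np.array_equal(
            glszm_matrix(gray, mask, levels=3), oracles.glszm_matrix_naive(gray, mask, 3)
        )

    def test_monotone_relabeling_preserves_zone_structure(self):
        rng = np.random.default_rng(4)
        gray, mask = _rand_raster(rng, levels=3)
        relabeled = np.array([0, 3, 5])[gray]  # strictly increasing map
        a = glszm_matrix(gray, mask, levels=3)
        b = glszm_matrix(relabeled, mask, levels=6)
        # same zone sizes per rank of gray level
        assert np.array_equal(a[[0, 1, 2], :], b[[0, 3, 5], :])


class TestDwt:
    def test_constant_image_all_zero(self):
        out = dwt_features(np.full((8, 8), 7.0), np.ones((8, 8), bool))
        assert all(v == 0 for v in out.values())

    def test_vertical_step_excites_hl(self):
        img = np.zeros((8, 8))
        img[:, 3:] = 100.0
        out = dwt_features(img, np.ones((8, 8), bool))
        assert out["dwt_HL_mean"] > 10 * max(out["dwt_LH_mean"], 1e-12)

    def test_six_features(self, demo_crop_mask):
        crop, mask = demo_crop_mask
        from viascreen.features import to_gray

        assert len(dwt_features(to_gray(crop), mask)) == 6


class TestLbp:
    def test_constant_region_single_bin(self):
        out = lbp_features(np.full((8, 8), 5.0), np.ones((8, 8), bool))
        vals = np.array(list(out.values()))
        assert vals.sum() == pytest.approx(1.0)
        assert (vals > 0).sum() == 1

    def test_ten_bins(self, demo_crop_mask):
        crop, mask = demo_crop_mask
        from viascreen.features import to_gray

        out = lbp_features(to_gray(crop), mask)
        assert len(out) == 10
        assert sum(out.values()) == pytest.approx(1.0)

    def test_codes_match_interpolation_oracle_on_interior(self):
        rng = np.random.default_rng(5)
        from skimage.feature import local_binary_pattern

        for _ in range(10):
            gray = rng.integers(0, 256, (6, 6), dtype=np.uint8)
            codes = local_binary_pattern(gray, P=8, R=1, method="uniform")
            for r in range(1, 5):
                for c in range(1, 5):
                    assert codes[r, c] == oracles.lbp_uniform_code_naive(gray, r, c)


def test_quantize_equal_width_and_constant_guard():
    gray = np.array([[0.0, 50.0], [100.0, 255.0]])
    q = quantize(gray, np.ones((2, 2), bool), levels=4)
    assert q[0, 0] == 0 and q[1, 1] == 3
    assert quantize(np.full((3, 3), 9.0), np.ones((3, 3), bool), 16).max() == 0
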