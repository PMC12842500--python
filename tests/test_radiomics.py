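"""Discretization, wavelet sub-bands and texture features against
brute-force neighbor-scan and convolution oracles."""

import numpy as np
import pytest
import pywt

from stoneburden.image import VolumeImage
from stoneburden.radiomics import (DiscretizedVOI, discretize, extract_features,
                                   feature_table, first_order_features,
                                   gldm_features, gldm_matrix, ngtdm_features,
                                   ngtdm_matrix, wavelet_reconstruct,
                                   wavelet_subbands, zscore_normalize)

from _oracles import (gldm_bruteforce, ngtdm_complexity_bruteforce,
                      subband_bruteforce)


def _random_discretized(rng, shape=(4, 4, 2), n_levels=4, p_mask=0.8):
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[0, 0, 0] = True
    return DiscretizedVOI(levels=np.where(mask, levels, 0), mask=mask, bin_width=25.0)


class TestDiscretize:
    def test_constant_voi_is_single_level(self):
        d = discretize(np.full((3, 3, 3), 211.0))
        assert (d.levels[d.mask] == 1).all()

    def test_floor_arithmetic(self):
        vals = np.array([130.0, 154.0, 155.0]).reshape(3, 1, 1)
        d = discretize(vals, bin_width=25)
        assert list(d.levels[:, 0, 0]) == [1, 1, 2]

    def test_matches_per_voxel_recomputation(self, rng):
        vals = rng.normal(300, 90, size=(5, 3, 2))
        d = discretize(vals, bin_width=25)
        mn = vals.min()
        for idx in np.ndindex(vals.shape):
            assert d.levels[idx] == int((vals[idx] - mn) // 25) + 1

    def test_offset_invariance(self, rng):
        vals = rng.normal(300, 90, size=(4, 4, 2))
        d1 = discretize(vals)
        d2 = discretize(vals + 500.0)
        np.testing.assert_array_equal(d1.levels, d2.levels)

    def test_empty_voi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretize(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestWavelet:
    def test_constant_patch_high_bands_vanish(self):
        bands = wavelet_subbands(np.full((4, 5, 6), 7.0))
        for name, band in bands.items():
            if "H" in name:
                assert np.abs(band).max() < 1e-12

    def test_lll_of_constant_is_scaled_by_lowpass_gain(self):
        c = 7.0
        bands = wavelet_subbands(np.full((4, 4, 4), c))
        gain = float(np.sum(pywt.Wavelet("haar").dec_lo)) ** 3
        assert bands["LLL"] == pytest.approx(np.full((4, 4, 4), c * gain))

    def test_impulse_matches_direct_convolution_oracle(self):
        patch = np.zeros((4, 4, 3))
        patch[1, 2, 1] = 1.0
        w = pywt.Wavelet("haar")
        bands = wavelet_subbands(patch)
        for name, band in bands.items():
            oracle = subband_bruteforce(patch, name, w.dec_lo, w.dec_hi)
            np.testing.assert_allclose(band, oracle, atol=1e-12)

    def test_random_patch_matches_oracle(self, rng):
        patch = rng.normal(size=(5, 4, 3))
        w = pywt.Wavelet("haar")
        for name, band in wavelet_subbands(patch).items():
            np.testing.assert_allclose(
                band, subband_bruteforce(patch, name, w.dec_lo, w.dec_hi),
                atol=1e-12)

    def test_perfect_reconstruction(self, rng):
        patch = rng.normal(size=(6, 5, 4))
        rec = wavelet_reconstruct(wavelet_subbands(patch))
        np.testing.assert_allclose(rec, patch, atol=1e-9)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            wavelet_subbands(np.zeros((4, 1, 4)))


class TestGLDM:
    def test_mass_equals_voxel_count(self, rng):
        for _ in range(10):
            d = _random_discretized(rng)
            assert gldm_matrix(d).sum() == d.voxel_count

    def test_uniform_2x2x1_patch(self):
        # every voxel has 3 same-level neighbors -> dependence 4
        d = discretize(np.full((2, 2, 1), 300.0))
        feats = gldm_features(gldm_matrix(d, alpha=0))
        assert feats["Dependence Variance"] == 0.0
        assert feats["Small Dependence Emphasis"] == pytest.approx(1 / 16)

    def test_point_mass_features(self):
        P = np.zeros((2, 27), dtype=np.int64)
        P[1, 4] = 12  # all voxels share dependence j0 = 5
        feats = gldm_features(P)
        assert feats["Dependence Variance"] == 0.0
        assert feats["Small Dependence Emphasis"] == pytest.approx(1 / 25)

    def test_matches_bruteforce_on_random_patches(self, rng):
        for alpha in (0.0, 1.0):
            for _ in range(15):
                d = _random_discretized(rng, shape=(3, 3, 2))
                np.testing.assert_array_equal(
                    gldm_matrix(d, alpha), gldm_bruteforce(d.levels, d.mask, alpha))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gldm_features(np.zeros((2, 27), dtype=np.int64))


class TestNGTDM:
    def test_constant_voi_has_zero_complexity(self):
        d = discretize(np.full((3, 3, 2), 250.0))
        assert ngtdm_features(ngtdm_matrix(d))["Complexity"] == 0.0

    def test_single_voxel_convention(self):
        d = discretize(np.array([[[400.0]]]))
        assert ngtdm_features(ngtdm_matrix(d))["Complexity"] == 0.0

    def test_two_level_checkerboard_matches_hand_enumeration(self):
        # levels: [[1, 2], [2, 1]] in a 2x2x1 sheet; every voxel's neighbor
        # mean is (2 other-level + 1 same-level)/3, |diff| = 2/3
        vals = np.array([[[100.0], [125.0]], [[125.0], [100.0]]])
        d = discretize(vals, bin_width=25)
        m = ngtdm_matrix(d)
        assert m.n_valid == 4
        np.testing.assert_allclose(m.p, [0.5, 0.5])
        np.testing.assert_allclose(m.s, [4 / 3, 4 / 3])
        # complexity: only the (1,2)/(2,1) cross terms contribute
        expected = 2 * (1 * (0.5 * 4 / 3 + 0.5 * 4 / 3) / 1.0) / 4
        assert ngtdm_features(m)["Complexity"] == pytest.approx(expected)

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(10):
            m = ngtdm_matrix(_random_discretized(rng))
            if m.n_valid:
                assert m.p.sum() == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_patches(self, rng):
        for _ in range(15):
            d = _random_discretized(rng, shape=(4, 3, 2))
            assert ngtdm_features(ngtdm_matrix(d))["Complexity"] == pytest.approx(
                ngtdm_complexity_bruteforce(d.levels, d.mask))


class TestFirstOrder:
    def test_small_example(self):
        feats = first_order_features(np.array([1.0, 2.0]), (1, 1, 1))
        assert feats["Energy"] == 5.0
        assert feats["Total Energy"] == 5.0
        assert (feats["Minimum"], feats["Mean"], feats["Maximum"]) == (1.0, 1.5, 2.0)

    def test_zeros_have_zero_energy(self):
        assert first_order_features(np.zeros(10), (0.7, 0.7, 5.0))["Energy"] == 0.0

    def test_total_energy_scales_with_voxel_volume(self, rng):
        vals = rng.normal(300, 50, size=50)
        feats = first_order_features(vals, (0.7, 0.7, 5.0))
        assert feats["Energy"] == pytest.approx((vals ** 2).sum())
        assert feats["Total Energy"] == pytest.approx(2.45 * (vals ** 2).sum())

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            first_order_features(np.array([]), (1, 1, 1))


class TestExtractFeatures:
    def test_stable_name_set_and_finite_values(self, rng):
        img = VolumeImage(rng.normal(200, 80, size=(8, 8, 6)), (0.7, 0.7, 5.0))
        vox = np.argwhere(rng.random((8, 8, 6)) < 0.2)
        feats = extract_features(img, vox)
        families = {"first order", "GLDM", "NGTDM"}
        filters = {"original"} | {f"wavelet-{b}" for b in
                                  ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")}
        assert all(np.isfinite(v) for v in feats.values())
        got_filters = {name.split("-first order")[0].split("-GLDM")[0].split("-NGTDM")[0]
                       for name in feats}
        assert got_filters == filters
        assert any("wavelet-HHH-GLDM-Dependence Variance" == n for n in feats)
        assert any("wavelet-LLH-NGTDM-Complexity" == n for n in feats)
        assert any("wavelet-LHH-first order-Total Energy" == n for n in feats)

    def test_texture_features_invariant_to_hu_offset(self, rng):
        base = rng.normal(250, 60, size=(6, 6, 4))
        vox = np.argwhere(rng.random((6, 6, 4)) < 0.5)
        f1 = extract_features(VolumeImage(base, (1, 1, 1)), vox, wavelet_on=False)
        f2 = extract_features(VolumeImage(base + 137.0, (1, 1, 1)), vox, wavelet_on=False)
        for name in f1:
            if "GLDM" in name or "NGTDM" in name:
                assert f1[name] == pytest.approx(f2[name])

    def test_single_slice_stone_still_gets_wavelet_features(self, rng):
        img = VolumeImage(rng.normal(200, 40, size=(8, 8, 4)), (0.7, 0.7, 5.0))
        vox = np.array([[3, 3, 2], [3, 4, 2], [4, 3, 2]])  # single z-slice
        feats = extract_features(img, vox)
        assert "wavelet-HHH-GLDM-Dependence Variance" in feats


class TestZScore:
    def test_three_point_column(self):
        import pandas as pd
        out = zscore_normalize(pd.DataFrame({"f": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["f"], [-1.0, 0.0, 1.0])

    def test_idempotence(self, rng):
        import pandas as pd
        t = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        once = zscore_normalize(t)
        twice = zscore_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_random_table_is_standardized(self, rng):
        import pandas as pd
        t = pd.DataFrame(rng.normal(5, 3, size=(40, 4)))
        out = zscore_normalize(t)
        np.testing.assert_allclose(out.mean().to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(ddof=1).to_numpy(), 1.0, atol=1e-12)

    def test_constant_column_becomes_zero_with_warning(self, rng):
        import pandas as pd
        t = pd.DataFrame({"c": [3.0, 3.0, 3.0], "x": [1.0, 2.0, 4.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_normalize(t)
        assert (out["c"] == 0.0).all()
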