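import numpy as np
import pytest

from lsradiomics import ConfigurationError
from lsradiomics.texture import (
    TextureConfig,
    ar_features,
    extract_all,
    feature_names,
    glcm_features,
    glcm_matrix,
    gradient_features,
    histogram_features,
    rlm_features,
    standardize_gray,
    wavelet_features,
)


@pytest.fixture()
def rect_mask():
    return np.ones((20, 20), dtype=bool)


class TestStandardizeGray:
    def test_constant_roi_minmax_maps_to_bin_zero(self, rect_mask):
        q = standardize_gray(np.full((20, 20), 7.0), rect_mask, TextureConfig(standardization="minmax"))
        assert np.all(q == 0)

    def test_constant_roi_mu3sigma_maps_to_mid_level(self, rect_mask):
        q = standardize_gray(np.full((20, 20), 7.0), rect_mask, TextureConfig())
        assert np.all(q == 32)

    def test_uniform_span_minmax_is_identity_binning(self):
        img = np.tile(np.arange(64.0), (4, 1))
        q = standardize_gray(img, np.ones_like(img, bool), TextureConfig(standardization="minmax"))
        assert np.array_equal(q, np.tile(np.arange(64), (4, 1)))

    def test_mu3sigma_clips_outlier_to_bin_zero(self, rng):
        img = rng.normal(100.0, 10.0, (20, 20))
        mu, sd = img.mean(), img.std()
        img[0, 0] = mu - 6 * sd  # beyond the mu - 3 sigma clip
        q = standardize_gray(img, np.ones_like(img, bool), TextureConfig())
        assert q[0, 0] == 0

    def test_out_of_mask_is_sentinel(self, rng):
        img = rng.random((10, 10))
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        q = standardize_gray(img, mask)
        assert q.shape == (6, 6)
        assert np.all(q >= 0)


class TestGlcm:
    def test_constant_roi_degenerate_values(self):
        feats = glcm_features(np.zeros((16, 16), dtype=np.int64), TextureConfig(glcm_distances=(1, 2)))
        for d in (1, 2):
            for ang in ("0", "45", "90", "135"):
                assert feats[f"glcm.Contrast.d{d}.{ang}"] == 0.0
                assert feats[f"glcm.AngScMom.d{d}.{ang}"] == 1.0
                assert feats[f"glcm.Entropy.d{d}.{ang}"] == pytest.approx(0.0)

    def test_checkerboard_row_hand_built_matrix(self):
        """(0,1,0,1,...) at d=1, 0 deg gives P = [[0,.5],[.5,0]]:
        contrast 1, energy 0.5."""
        row = np.array([[0, 1] * 8], dtype=np.int64)
        p = glcm_matrix(row, 1, "0", levels=2)
        assert np.allclose(p, [[0.0, 0.5], [0.5, 0.0]])
        feats = glcm_features(row, TextureConfig(gray_levels=2, glcm_distances=(1,)))
        assert feats["glcm.Contrast.d1.0"] == 1.0
        assert feats["glcm.AngScMom.d1.0"] == 0.5

    def test_matrix_normalized_to_unit_sum(self, rng):
        q = rng.integers(0, 8, (12, 12))
        for ang in ("0", "45", "90", "135"):
            assert glcm_matrix(q, 2, ang, levels=8).sum() == pytest.approx(1.0)

    def test_direction_pooled_mean_invariant_under_transpose(self, rng):
        q = rng.integers(0, 8, (15, 15))
        cfg = TextureConfig(gray_levels=8, glcm_distances=(1, 3))
        a = glcm_features(q, cfg)
        b = glcm_features(q.T, cfg)
        for feat in ("Contrast", "Entropy", "AngScMom"):
            for d in (1, 3):
                pooled_a = np.mean([a[f"glcm.{feat}.d{d}.{ang}"] for ang in ("0", "45", "90", "135")])
                pooled_b = np.mean([b[f"glcm.{feat}.d{d}.{ang}"] for ang in ("0", "45", "90", "135")])
                assert pooled_a == pytest.approx(pooled_b)

    def test_roi_thinner_than_distance_skips_matrix(self):
        row = np.array([[0, 1, 2]], dtype=np.int64)
        feats = glcm_features(row, TextureConfig(gray_levels=4, glcm_distances=(5,)))
        assert feats == {}


class TestRlm:
    def test_single_run_in_constant_line(self):
        q = np.zeros((1, 12), dtype=np.int64)
        feats = rlm_features(q)
        assert feats["rlm.Fraction.0"] == pytest.approx(1 / 12)
        assert feats["rlm.LngREmph.0"] == pytest.approx(144.0)

    def test_alternating_row_all_unit_runs(self):
        q = np.array([[0, 1] * 10], dtype=np.int64)
        feats = rlm_features(q)
        assert feats["rlm.ShrtREmp.0"] == 1.0
        assert feats["rlm.Fraction.0"] == 1.0

    def test_run_percentage_bounds(self, rng):
        q = rng.integers(0, 4, (16, 16))
        feats = rlm_features(q)
        for ang in ("0", "45", "90", "135"):
            assert 0.0 < feats[f"rlm.Fraction.{ang}"] <= 1.0


class TestFirstOrderFamilies:
    def test_constant_roi_zero_properties(self):
        q = np.full((16, 16), 5, dtype=np.int64)
        h = histogram_features(q)
        assert h["hist.Variance"] == h["hist.Skewness"] == h["hist.Kurtosis"] == 0.0
        g = gradient_features(q)
        assert g["grad.GrMean"] == 0.0 and g["grad.GrNonZeros"] == 0.0
        w = wavelet_features(q)
        for lvl in (1, 2, 3):
            for band in ("LH", "HL", "HH"):
                assert w[f"wavelet.En{band}.l{lvl}"] == 0.0

    def test_symmetric_noise_has_small_skewness(self, rng):
        q = rng.integers(0, 64, (100, 100))
        assert abs(histogram_features(q)["hist.Skewness"]) < 0.2

    def test_ar_parameters_recovered_exactly_on_noiseless_field(self):
        """A field generated by the causal AR recursion (zero driving noise)
        is fit exactly: parameters recovered to 1e-6."""
        theta = (0.4, 0.3, 0.2, 0.05)
        rng = np.random.default_rng(3)
        f = np.zeros((40, 40))
        f[0, :] = rng.uniform(1, 2, 40)
        f[:, 0] = rng.uniform(1, 2, 40)
        f[:, -1] = rng.uniform(1, 2, 40)
        for i in range(1, 40):
            for j in range(1, 39):
                f[i, j] = (
                    theta[0] * f[i, j - 1]
                    + theta[1] * f[i - 1, j - 1]
                    + theta[2] * f[i - 1, j]
                    + theta[3] * f[i - 1, j + 1]
                )
        feats = ar_features(f)
        for k, want in enumerate(theta, start=1):
            assert feats[f"ar.Teta{k}"] == pytest.approx(want, abs=1e-6)
        assert feats["ar.Sigma"] == pytest.approx(0.0, abs=1e-6)

    def test_ar_skipped_on_tiny_roi(self):
        assert ar_features(np.zeros((2, 2), dtype=np.int64)) == {}


class TestExtractAll:
    def test_deterministic_and_schema_length(self, disk_phantom):
        _, img, mask = disk_phantom
        a = extract_all(img, mask)
        b = extract_all(img, mask)
        assert a.equals(b)
        assert list(a.index) == feature_names()
        assert len(a) == 271
        assert np.all(np.isfinite(a.to_numpy()))

    def test_histogram_invariant_glcm_sensitive_to_pixel_shuffle(self, rng):
        """Shuffling in-mask pixels preserves first-order statistics but
        destroys spatial co-occurrence structure."""
        img = np.tile(np.arange(32.0), (32, 1))  # strong horizontal ramp
        mask = np.ones((32, 32), bool)
        cfg = TextureConfig(gray_levels=16, standardization="minmax", glcm_distances=(1,))
        q = standardize_gray(img, mask, cfg)
        shuffled = q.copy().ravel()
        rng.shuffle(shuffled)
        shuffled = shuffled.reshape(q.shape)
        assert histogram_features(q) == histogram_features(shuffled)
        orig = glcm_features(q, cfg)["glcm.Contrast.d1.0"]
        shuf = glcm_features(shuffled, cfg)["glcm.Contrast.d1.0"]
        assert abs(orig - shuf) > 1.0

    def test_erode_margin_shrinks_roi(self, disk_phantom):
        _, img, mask = disk_phantom
        q0 = standardize_gray(img, mask, TextureConfig())
        q2 = standardize_gray(img, mask, TextureConfig(erode=2))
        assert (q2 >= 0).sum() < (q0 >= 0).sum()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            TextureConfig(gray_levels=1)
        with pytest.raises(ConfigurationError):
            TextureConfig(glcm_distances=(0,))
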