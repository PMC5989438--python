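"""Feature extraction: HOG, reduction, GLCM texture, color moments, fusion."""

import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops

from lesionpipe.features import (
    COLOR_LENGTH,
    FUSED_LENGTH,
    GLCM_ANGLES,
    GLCM_LEVELS,
    HOG_LENGTH,
    HOG_WINDOW,
    HogEntropyReducer,
    _moments,
    color_feature_names,
    color_moments,
    crop_and_resize,
    extract_hog,
    glcm_features,
    parallel_fuse,
    texture_feature_names,
    zero_pad,
    TEXTURE_LENGTH,
)


class TestCropAndResize:
    def test_centered_disc(self):
        yy, xx = np.mgrid[0:100, 0:100]
        mask = (((yy - 50) ** 2 + (xx - 50) ** 2) <= 400).astype(np.uint8)
        img = np.full((100, 100, 3), 100.0)
        crop = crop_and_resize(img, mask)
        assert crop.shape == (*HOG_WINDOW, 3)
        # background zeroed: corners of the crop are outside the disc
        assert crop[0, 0].sum() == 0

    def test_full_mask_whole_image(self):
        img = np.random.default_rng(0).uniform(0, 255, (64, 64, 3))
        crop = crop_and_resize(img, np.ones((64, 64), dtype=np.uint8))
        assert crop.shape == (*HOG_WINDOW, 3)
        assert crop.sum() > 0

    def test_tiny_mask_no_crash(self):
        img = np.full((50, 50, 3), 90.0)
        mask = np.zeros((50, 50), dtype=np.uint8)
        mask[25, 25:27] = 1
        crop = crop_and_resize(img, mask)
        assert crop.shape == (*HOG_WINDOW, 3)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty mask"):
            crop_and_resize(np.zeros((32, 32, 3)), np.zeros((32, 32), dtype=np.uint8))


class TestHog:
    def test_length_3780(self, rng):
        crop = rng.uniform(0, 255, (*HOG_WINDOW, 3))
        assert extract_hog(crop).shape == (HOG_LENGTH,)

    def test_constant_crop_zero_descriptor(self):
        assert np.all(extract_hog(np.full(HOG_WINDOW, 55.0)) == 0)

    def test_vertical_step_edge_orientation(self):
        """Dominant orientation bin matches a hand-computed cell histogram."""
        img = np.zeros(HOG_WINDOW)
        img[:, 32:] = 200.0
        vec = extract_hog(img)
        # 15 x 7 blocks x 2 x 2 cells x 9 orientations
        per_orient = vec.reshape(-1, 9).sum(axis=0)
        dominant = int(np.argmax(per_orient))
        # oracle: central differences, orientation = atan2(gy, gx) mod 180,
        # magnitude-weighted histogram in 9 bins of 20 degrees
        gy, gx = np.zeros_like(img), np.zeros_like(img)
        gy[1:-1, :] = img[2:, :] - img[:-2, :]
        gx[:, 1:-1] = img[:, 2:] - img[:, :-2]
        mag = np.hypot(gx, gy)
        orient = np.rad2deg(np.arctan2(gy, gx)) % 180
        hist = np.zeros(9)
        for o, m in zip(orient.ravel(), mag.ravel()):
            if m > 0:
                hist[int(o // 20) % 9] += m
        assert dominant == int(np.argmax(hist))
        assert per_orient[dominant] / per_orient.sum() > 0.9

    def test_block_subvectors_l2hys_bounded(self, rng):
        vec = extract_hog(rng.uniform(0, 255, HOG_WINDOW))
        for blk in vec.reshape(-1, 36):
            assert np.linalg.norm(blk) <= 1.0 + 1e-6


class TestHogEntropyReducer:
    def test_selects_exactly_n_keep(self, rng):
        X = rng.uniform(0, 1, (12, 300))
        red = HogEntropyReducer(n_keep=200).fit(X)
        assert red.selected_idx_.shape == (200,)
        assert red.transform(X).shape == (12, 200)

    def test_deterministic(self, rng):
        X = rng.uniform(0, 1, (10, 250))
        a = HogEntropyReducer(n_keep=200).fit(X).selected_idx_
        b = HogEntropyReducer(n_keep=200).fit(X).selected_idx_
        assert np.array_equal(a, b)

    def test_constant_columns_never_selected(self, rng):
        n_inf = 20
        X = np.zeros((30, 120))
        X[:, :n_inf] = rng.normal(0, 5, (30, n_inf))
        red = HogEntropyReducer(n_keep=n_inf).fit(X)
        assert set(red.selected_idx_) == set(range(n_inf))

    def test_score_recomputation_oracle(self, rng):
        """Scores equal an independent numpy-SVD straight-line recomputation."""
        X = rng.uniform(0, 3, (15, 40))
        red = HogEntropyReducer(n_keep=10, n_bins=16).fit(X)
        # PCA importance via raw SVD
        Xc = X - X.mean(axis=0)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        evr = s**2 / (s**2).sum()
        ncomp = min(X.shape) - 1
        w = (np.abs(Vt[:ncomp]).T * evr[:ncomp]).sum(axis=1)
        w = (w - w.min()) / (w.max() - w.min())
        ent = []
        for col in X.T:
            counts, _ = np.histogram(col, bins=16, range=(col.min(), col.max()))
            p = counts[counts > 0] / counts.sum()
            ent.append(-(p * np.log2(p)).sum())
        scores = w * np.array(ent)
        assert np.allclose(red.scores_, scores, atol=1e-9)
        expect = np.sort(np.argsort(-scores, kind="stable")[:10])
        assert np.array_equal(red.selected_idx_, expect)

    def test_too_few_features_errors(self, rng):
        with pytest.raises(ValueError, match="cannot keep"):
            HogEntropyReducer(n_keep=200).fit(rng.uniform(0, 1, (5, 50)))


class TestGlcm:
    def test_length_42(self, rng):
        gray = rng.uniform(0, 255, (40, 40))
        mask = np.ones((40, 40), dtype=np.uint8)
        vec = glcm_features(gray, mask)
        assert vec.shape == (TEXTURE_LENGTH,)
        assert len(texture_feature_names()) == TEXTURE_LENGTH

    def test_constant_region_degenerate(self):
        vec = glcm_features(np.full((20, 20), 77.0), np.ones((20, 20), dtype=np.uint8))
        names = texture_feature_names()
        v = dict(zip(names, vec))
        assert v["tex_energy_mean"] == 1.0
        assert v["tex_entropy_mean"] == 0.0
        assert v["tex_contrast_mean"] == 0.0
        # all ranges and variances vanish for a single-cell GLCM
        assert all(v[n] == 0 for n in names if n.endswith(("range", "var")))

    def test_checkerboard_contrast_enumeration(self):
        """4x4 two-level checkerboard: horizontal and vertical neighbours
        always differ by the full quantized span (31 levels), diagonal
        neighbours never differ -> contrast per offset is (961, 0, 961, 0)."""
        board = np.indices((4, 4)).sum(axis=0) % 2 * 255.0
        vec = glcm_features(board, np.ones((4, 4), dtype=np.uint8))
        v = dict(zip(texture_feature_names(), vec))
        per_offset = np.array([961.0, 0.0, 961.0, 0.0])
        assert v["tex_contrast_mean"] == pytest.approx(per_offset.mean())
        assert v["tex_contrast_range"] == pytest.approx(961.0)
        assert v["tex_contrast_var"] == pytest.approx(per_offset.var())

    def test_overlapping_stats_match_graycoprops(self, rng):
        """Library oracle for the stats skimage also implements."""
        gray = rng.uniform(0, 255, (30, 30))
        mask = np.ones((30, 30), dtype=np.uint8)
        vec = glcm_features(gray, mask)
        v = dict(zip(texture_feature_names(), vec))
        lo, hi = gray.min(), gray.max()
        quant = np.floor((gray - lo) / (hi - lo) * (GLCM_LEVELS - 1e-9)).astype(np.uint8)
        glcm = graycomatrix(quant, [1], list(GLCM_ANGLES), levels=GLCM_LEVELS,
                            symmetric=True, normed=True)
        for stat, name in [("contrast", "tex_contrast_mean"),
                           ("dissimilarity", "tex_dissimilarity_mean"),
                           ("homogeneity", "tex_homog2_mean")]:
            ref = graycoprops(glcm, stat)[0].mean()
            assert v[name] == pytest.approx(ref, abs=1e-9)

    def test_energy_entropy_invariants(self, rng):
        gray = rng.uniform(0, 255, (25, 25))
        v = dict(zip(texture_feature_names(),
                     glcm_features(gray, np.ones((25, 25), dtype=np.uint8))))
        assert 0 < v["tex_energy_mean"] <= 1
        assert v["tex_entropy_mean"] >= 0

    def test_region_too_small_errors(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[5, 5] = 1
        with pytest.raises(ValueError, match="4 pixels"):
            glcm_features(np.zeros((10, 10)), mask)


class TestColorMoments:
    def test_length_36(self, rng):
        img = rng.uniform(0, 255, (20, 20, 3))
        vec = color_moments(img, np.ones((20, 20), dtype=np.uint8))
        assert vec.shape == (COLOR_LENGTH,)
        assert len(color_feature_names()) == COLOR_LENGTH

    def test_constant_region_zero_higher_moments(self):
        img = np.full((10, 10, 3), 99.0)
        vec = color_moments(img, np.ones((10, 10), dtype=np.uint8))
        v = dict(zip(color_feature_names(), vec))
        for name, val in v.items():
            if name.endswith(("var", "skew", "kurt")):
                assert val == 0.0

    def test_four_value_moment_oracle(self):
        mean, var, skew, kurt = _moments(np.array([10.0, 20.0, 30.0, 40.0]))
        assert mean == 25.0
        assert var == 125.0
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(-1.36)

    def test_direct_summation_oracle(self, rng):
        """RGB moments match direct formula evaluation on a small region."""
        img = rng.uniform(0, 255, (10, 10, 3))
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[:5, :5] = 1
        vec = color_moments(img, mask)
        v = dict(zip(color_feature_names(), vec))
        px = img[:5, :5, 0].ravel()
        m = px.mean()
        var = ((px - m) ** 2).mean()
        skew = ((px - m) ** 3).mean() / var**1.5
        kurt = ((px - m) ** 4).mean() / var**2 - 3
        assert v["col_rgb_r_mean"] == pytest.approx(m, abs=1e-9)
        assert v["col_rgb_r_var"] == pytest.approx(var, abs=1e-9)
        assert v["col_rgb_r_skew"] == pytest.approx(skew, abs=1e-9)
        assert v["col_rgb_r_kurt"] == pytest.approx(kurt, abs=1e-9)

    def test_variances_nonnegative(self, rng):
        img = rng.uniform(0, 255, (15, 15, 3))
        v = dict(zip(color_feature_names(),
                     color_moments(img, np.ones((15, 15), dtype=np.uint8))))
        assert all(val >= 0 for name, val in v.items() if name.endswith("var"))

    def test_region_too_small_errors(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        with pytest.raises(ValueError, match="2 pixels"):
            color_moments(np.zeros((5, 5, 3)), mask)


class TestParallelFuse:
    def test_padding_exact_zeros(self, rng):
        t = rng.uniform(0, 1, TEXTURE_LENGTH)
        c = rng.uniform(0, 1, COLOR_LENGTH)
        assert np.all(zero_pad(t, FUSED_LENGTH)[TEXTURE_LENGTH:] == 0)
        assert np.all(zero_pad(c, FUSED_LENGTH)[COLOR_LENGTH:] == 0)

    def test_reduces_to_twice_abs_hog(self, rng):
        h = rng.normal(0, 1, FUSED_LENGTH)
        fused = parallel_fuse(h, np.zeros(TEXTURE_LENGTH), np.zeros(COLOR_LENGTH))
        assert np.allclose(fused, 2 * np.abs(h))

    def test_pythagorean_case(self):
        h = np.zeros(FUSED_LENGTH)
        t = np.zeros(TEXTURE_LENGTH)
        c = np.zeros(COLOR_LENGTH)
        h[0], t[0], c[0] = 3.0, 4.0, 0.0
        fused = parallel_fuse(h, t, c)
        assert fused[0] == pytest.approx(8.0)  # 5 + 3
        assert fused.shape == (FUSED_LENGTH,)

    def test_wrong_lengths_error(self):
        with pytest.raises(ValueError, match="expected lengths"):
            parallel_fuse(np.zeros(100), np.zeros(TEXTURE_LENGTH),
                          np.zeros(COLOR_LENGTH))
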