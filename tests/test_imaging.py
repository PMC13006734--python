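"""Tests for the micromarker detection pipeline."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.filters import threshold_otsu as sk_otsu

from strainspeech import imaging, synthfab
from strainspeech.imaging import DetectConfig


def _bimodal_image(rng, lo=40, hi=220, shape=(60, 80)):
    img = np.full(shape, hi, dtype=np.uint8)
    mask = rng.random(shape) < 0.3
    img[mask] = lo
    return img


def brute_force_otsu(img: np.ndarray) -> int:
    """Independent exhaustive Otsu: maximize between-class variance."""
    vals = img.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(256):
        c0 = vals[vals <= t]
        c1 = vals[vals > t]
        if len(c0) == 0 or len(c1) == 0:
            continue
        v = len(c0) * len(c1) * (c0.mean() - c1.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestEnhanceContrast:
    def test_constant_image_unchanged(self):
        img = np.full((40, 40), 99, dtype=np.uint8)
        out = imaging.enhance_contrast(img)
        assert np.array_equal(out, img)

    def test_two_level_image_spread_toward_extremes(self):
        rng = np.random.default_rng(0)
        img = _bimodal_image(rng)
        out = imaging.enhance_contrast(img)
        assert out.min() <= img.min()
        assert out.max() >= img.max()

    def test_range_contract_on_random_images(self):
        rng = np.random.default_rng(1)
        for _ in range(3):
            img = rng.integers(0, 256, size=(50, 50)).astype(np.uint8)
            out = imaging.enhance_contrast(img)
            assert out.shape == img.shape
            assert out.min() >= 0 and out.max() <= 255


class TestSharpen:
    def test_zero_sum_kernel_annihilates_constant(self):
        cfg = DetectConfig()
        cfg.sharpen_kernel = np.array([[-1, -1, -1], [-1, 8, -1], [-1, -1, -1]], dtype=float)
        img = np.full((30, 30), 120, dtype=np.uint8)
        out = imaging.sharpen(img, cfg)
        assert np.all(out == 0)

    def test_step_edge_gradient_increases(self):
        img = np.zeros((40, 40), dtype=np.uint8)
        img[:, 20:] = 200
        out = imaging.sharpen(img).astype(float)
        grad_before = np.abs(np.diff(img.astype(float), axis=1)).max()
        grad_after = np.abs(np.diff(out, axis=1)).max()
        assert grad_after >= grad_before

    def test_interior_pixel_matches_bruteforce_chain(self):
        """The full sharpen chain at one interior pixel equals an independent
        recomputation (unsharp -> blur -> hand 3x3 weighted sum)."""
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
        cfg = DetectConfig()
        out = imaging.sharpen(img, cfg)

        f = img.astype(float)
        blurred = ndimage.gaussian_filter(f, 1.0, mode="nearest")
        unsharp = 2 * f - blurred
        den = ndimage.gaussian_filter(unsharp, cfg.gaussian_sigma, mode="nearest")
        k = cfg.sharpen_kernel
        y, x = 10, 10
        acc = 0.0
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                acc += den[y + dy, x + dx] * k[1 + dy, 1 + dx]
        expected = np.clip(np.rint(acc), 0, 255)
        assert out[y, x] == expected

    def test_non_3x3_kernel_raises(self):
        cfg = DetectConfig()
        cfg.sharpen_kernel = np.ones((5, 5))
        with pytest.raises(ValueError, match="3x3"):
            imaging.sharpen(np.zeros((10, 10), dtype=np.uint8), cfg)


class TestRemoveBorder:
    def test_margin_zero_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        assert np.array_equal(imaging.remove_border(img, 0), img)

    def test_black_image_whitened_border(self):
        img = np.zeros((50, 60), dtype=np.uint8)
        out = imaging.remove_border(img, 10)
        assert np.all(out[:10] == 255) and np.all(out[-10:] == 255)
        assert np.all(out[:, :10] == 255) and np.all(out[:, -10:] == 255)
        assert np.all(out[10:-10, 10:-10] == 0)

    def test_margin_too_large_raises(self):
        with pytest.raises(ValueError, match="margin"):
            imaging.remove_border(np.zeros((20, 20), dtype=np.uint8), 10)


class TestBinarize:
    def test_matches_bruteforce_otsu_on_bimodal(self):
        rng = np.random.default_rng(3)
        img = _bimodal_image(rng)
        t = imaging.otsu_threshold(img)
        assert t == brute_force_otsu(img)
        assert 40 <= t < 220

    def test_matches_bruteforce_on_random_images(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            img = rng.integers(0, 256, size=(30, 30)).astype(np.uint8)
            assert imaging.otsu_threshold(img) == brute_force_otsu(img)

    def test_agrees_with_skimage_partition(self):
        """Independent cross-check: the induced partition matches the one
        from scikit-image's Otsu on a well-separated bimodal image."""
        rng = np.random.default_rng(5)
        img = _bimodal_image(rng)
        ours = imaging.binarize(img)
        theirs = img <= sk_otsu(img)
        assert np.array_equal(ours, theirs)

    def test_already_binary_classes_preserved(self):
        rng = np.random.default_rng(6)
        img = np.where(rng.random((40, 40)) < 0.4, 0, 255).astype(np.uint8)
        out = imaging.binarize(img)
        assert np.array_equal(out, img == 0)

    def test_inversion_swaps_foreground_background(self):
        rng = np.random.default_rng(7)
        img = _bimodal_image(rng)
        fg = imaging.binarize(img)
        fg_inv = imaging.binarize(255 - img)
        assert np.array_equal(fg_inv, ~fg)

    def test_constant_image_all_background(self, caplog):
        img = np.full((20, 20), 50, dtype=np.uint8)
        with caplog.at_level("WARNING"):
            out = imaging.binarize(img)
        assert not out.any()
        assert "constant" in caplog.text


class TestExtractMarkers:
    def test_empty_binary_image(self):
        out = imaging.extract_markers(np.zeros((30, 30), dtype=bool))
        assert len(out) == 0

    def test_counts_rendered_circles(self, grid5x5):
        img = synthfab.render_marker_image(grid5x5, synthfab.DeformationField.identity())
        binary = img < 128
        ms = imaging.extract_markers(binary, DetectConfig(min_area_px=20, max_area_px=500))
        assert len(ms) == 25

    def test_speck_is_filtered(self):
        binary = np.zeros((60, 60), dtype=bool)
        binary[5:7, 5:7] = True  # 4-px speck
        yy, xx = np.mgrid[:60, :60]
        binary |= (yy - 30) ** 2 + (xx - 30) ** 2 <= 36
        ms = imaging.extract_markers(binary, DetectConfig(min_area_px=20, max_area_px=500))
        assert len(ms) == 1
        assert np.allclose(ms.centroids[0], (30, 30), atol=0.5)

    def test_min_area_monotonicity(self, grid5x5):
        img = synthfab.render_marker_image(grid5x5, synthfab.DeformationField.identity())
        binary = img < 128
        counts = [
            len(imaging.extract_markers(binary, DetectConfig(min_area_px=m, max_area_px=500)))
            for m in (1, 20, 80, 120)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDetectMarkers:
    def test_blank_frame_empty_set(self):
        img = np.full((240, 320), 235, dtype=np.uint8)
        assert len(imaging.detect_markers(img)) == 0

    def test_clean_frame_centroids_within_one_pixel(self, grid5x5):
        img = synthfab.render_marker_image(grid5x5, synthfab.DeformationField.identity())
        ms = imaging.detect_markers(img)
        assert len(ms) == 25
        from scipy.spatial import cKDTree

        d, _ = cKDTree(grid5x5.marker_centers()).query(ms.centroids)
        assert d.max() < 1.0

    def test_noisy_frame_recall(self, substrate):
        rng = np.random.default_rng(8)
        img = synthfab.render_marker_image(
            substrate, synthfab.DeformationField.identity(), noise_sd=8, rng=rng
        )
        ms = imaging.detect_markers(img)
        from scipy.spatial import cKDTree

        true = substrate.marker_centers()
        if len(ms) == 0:
            recovered = 0
        else:
            d, _ = cKDTree(ms.centroids).query(true)
            recovered = int((d < 3.0).sum())
        assert recovered / len(true) >= 0.9

    def test_vignette_ring_produces_no_edge_boxes(self, grid5x5):
        img = synthfab.render_marker_image(grid5x5, synthfab.DeformationField.identity()).astype(float)
        yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
        edge = np.minimum.reduce([yy, xx, img.shape[0] - 1 - yy, img.shape[1] - 1 - xx])
        img[edge < 3] = 5  # dark vignette
        ms = imaging.detect_markers(img.astype(np.uint8))
        for b in ms.boxes:
            assert b.x > 0 and b.y > 0
            assert b.x + b.w < img.shape[1] and b.y + b.h < img.shape[0]

    def test_pipeline_deterministic(self, identity_frame):
        a = imaging.detect_markers(identity_frame)
        b = imaging.detect_markers(identity_frame)
        assert np.array_equal(a.centroids, b.centroids)
        assert np.array_equal(a.areas, b.areas)
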