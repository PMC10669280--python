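"""Adaptive Wiener filter, Sobel gradient, segmentation, and FCCP response."""

import numpy as np
import pytest

from mitoquant.imaging import (
    SegmentationConfig,
    adaptive_wiener,
    auto_threshold,
    bright_area_ratio,
    fccp_response,
    gradient_magnitude,
    segment_mitochondria,
)
from mitoquant.morphology import structuring_element
from oracles import dilate_oracle, erode_oracle, sobel_oracle, wiener_oracle


class TestAdaptiveWiener:
    def test_constant_image_is_fixed_point(self):
        img = np.full((12, 12), 7.0)
        np.testing.assert_array_equal(adaptive_wiener(img, (5, 5)), img)

    def test_centre_spike_matches_sliding_window_oracle(self):
        img = np.zeros((7, 7))
        img[3, 3] = 49.0
        out = adaptive_wiener(img, (3, 3))
        np.testing.assert_allclose(out, wiener_oracle(img, (3, 3)), atol=1e-9)

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(5):
            img = rng.uniform(0, 50, size=rng.integers(5, 12, size=2))
            np.testing.assert_allclose(
                adaptive_wiener(img, (3, 3)), wiener_oracle(img, (3, 3)), atol=1e-9
            )

    def test_reduces_noise_on_flat_field(self):
        g = np.random.default_rng(99)
        img = np.clip(100.0 + g.normal(0, 10, (128, 128)), 0, None)
        out = adaptive_wiener(img, (5, 5))
        assert np.mean((out - 100.0) ** 2) < np.mean((img - 100.0) ** 2)

    @pytest.mark.parametrize("window", [(4, 5), (5, 4), (1, 5)])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ValueError):
            adaptive_wiener(np.ones((10, 10)), window)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            adaptive_wiener(np.ones((5, 5)), (7, 7))

    def test_negative_or_nonfinite_pixels_rejected(self):
        with pytest.raises(ValueError):
            adaptive_wiener(np.full((5, 5), -1.0), (3, 3))
        bad = np.ones((5, 5))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            adaptive_wiener(bad, (3, 3))


class TestGradient:
    def test_constant_image_has_zero_gradient(self):
        assert gradient_magnitude(np.full((9, 9), 3.5)).max() == 0.0

    def test_vertical_step_magnitude_is_4h_at_edge(self):
        h = 11.0
        img = np.zeros((6, 6))
        img[:, 3:] = h
        grad = gradient_magnitude(img)
        # columns adjacent to the step (interior rows) carry magnitude 4h
        np.testing.assert_allclose(grad[1:-1, 2], 4 * h)
        np.testing.assert_allclose(grad[1:-1, 3], 4 * h)
        np.testing.assert_allclose(grad[:, 0], 0.0)
        np.testing.assert_allclose(grad[:, -1], 0.0)

    def test_single_bright_pixel_matches_convolution_oracle(self):
        img = np.zeros((7, 7))
        img[3, 3] = 10.0
        np.testing.assert_allclose(gradient_magnitude(img), sobel_oracle(img), atol=1e-9)

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(5):
            img = rng.uniform(0, 20, size=(6, 8))
            np.testing.assert_allclose(gradient_magnitude(img), sobel_oracle(img), atol=1e-9)


class TestAutoThreshold:
    def test_uniform_gradient_scales_mean(self):
        grad = np.full((4, 4), 2.5)
        assert auto_threshold(grad, 4.0) == pytest.approx(10.0)

    def test_zero_gradient_gives_zero(self):
        assert auto_threshold(np.zeros((4, 4)), 4.0) == 0.0

    def test_mixed_grid_equals_scaled_arithmetic_mean(self):
        grad = np.arange(16, dtype=float).reshape(4, 4)
        assert auto_threshold(grad, 3.0) == pytest.approx(3.0 * 7.5)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            auto_threshold(np.ones((3, 3)), 0.0)


class TestSegmentation:
    def test_constant_image_yields_zero_regions_flagged(self):
        res = segment_mitochondria(np.full((32, 32), 40.0))
        assert res.n_regions == 0
        assert res.segmented_area_px == 0
        assert res.bright_ratio is None

    def test_bright_square_single_region_with_faithful_mean(self):
        img = np.full((32, 32), 10.0)
        img[13:19, 13:19] = 200.0
        cfg = SegmentationConfig()
        res = segment_mitochondria(img, cfg)
        assert res.n_regions == 1
        assert abs(res.region_means[0][1] - 200.0) / 200.0 < 0.05
        true_mask = img > 10.0
        dil = dilate_oracle(
            dilate_oracle(true_mask, structuring_element("lines", 1)[0]),
            structuring_element("lines", 1)[1],
        )
        ero = erode_oracle(true_mask, structuring_element("diamond", cfg.erosion_radius)[0])
        assert ero.sum() <= res.segmented_area_px <= dil.sum()

    def test_pipeline_is_deterministic_and_shape_preserving(self, rng):
        img = rng.uniform(0, 100, (40, 40))
        r1 = segment_mitochondria(img)
        r2 = segment_mitochondria(img.copy())
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.region_means == r2.region_means
        assert r1.bright_ratio == r2.bright_ratio
        assert r1.labels.shape == img.shape == r1.filtered.shape

    def test_region_ids_consecutive_sorted_by_area(self):
        img = np.full((40, 40), 5.0)
        img[5:9, 5:9] = 200.0      # small square
        img[20:32, 18:34] = 200.0  # large rectangle
        res = segment_mitochondria(img)
        ids = [rid for rid, _ in res.region_areas]
        areas = [a for _, a in res.region_areas]
        assert ids == list(range(1, res.n_regions + 1))
        assert areas == sorted(areas, reverse=True)
        assert res.segmented_area_px == sum(areas)
        assert 0 <= res.bright_area_px <= res.segmented_area_px


class TestBrightAreaRatio:
    def test_all_pixels_at_max_gives_one(self):
        img = np.full((5, 5), 9.0)
        mask = np.ones((5, 5), dtype=bool)
        assert bright_area_ratio(img, mask) == 1.0

    def test_half_at_max_half_dim_gives_half(self):
        img = np.full((4, 4), 0.2 * 50.0)
        img[:2] = 50.0
        assert bright_area_ratio(img, np.ones((4, 4), bool)) == 0.5

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no segmented signal"):
            bright_area_ratio(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestFccpResponse:
    def test_formula_and_identity(self):
        assert fccp_response(100.0, 25.0).response_pct == pytest.approx(75.0)
        assert fccp_response(42.0, 42.0).response_pct == pytest.approx(0.0)

    def test_rising_signal_gives_negative_response(self):
        assert fccp_response(50.0, 60.0).response_pct == pytest.approx(-20.0)

    def test_no_pre_uncoupler_signal_rejected(self):
        with pytest.raises(ValueError):
            fccp_response(0.0, 10.0)
        with pytest.raises(ValueError):
            fccp_response(-5.0, 1.0)
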