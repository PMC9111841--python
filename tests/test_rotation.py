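"""Deskew estimation: Sobel gradients, folded direction histogram, rotation."""

import numpy as np
import pytest

from mycoquant import (
    DirectionHistogram,
    SlideImage,
    SlidePhantomSpec,
    compute_gradients,
    direction_histogram,
    estimate_rotation_angle,
    generate_slide,
    normalize_rotation,
    rotate_image,
    rotate_points,
)
from mycoquant.rotation import estimate_rotation

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)


def _loop_sobel(lum, kernel):
    """Brute-force 3x3 correlation with edge-reflection padding."""
    padded = np.pad(lum, 1, mode="symmetric")
    out = np.zeros_like(lum, dtype=float)
    for i in range(lum.shape[0]):
        for j in range(lum.shape[1]):
            out[i, j] = (padded[i : i + 3, j : j + 3] * kernel).sum()
    return out


class TestGradients:
    def test_constant_image_zero_gradient(self):
        g = compute_gradients(np.full((20, 20, 3), 128, np.uint8))
        assert np.all(g.gx == 0) and np.all(g.gy == 0)

    def test_vertical_step_edge(self):
        px = np.zeros((20, 20, 3), np.uint8)
        px[:, 10:] = 255
        g = compute_gradients(px)
        assert np.abs(g.gx[:, 9:11]).min() > 0
        assert np.all(g.gy[1:-1] == 0)

    def test_matches_loop_oracle_on_random_raster(self, rng):
        lum = rng.uniform(0, 255, (8, 8))
        g = compute_gradients(lum)
        np.testing.assert_allclose(g.gx, _loop_sobel(lum, SOBEL_X), atol=1e-9)
        np.testing.assert_allclose(g.gy, _loop_sobel(lum, SOBEL_X.T), atol=1e-9)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            compute_gradients(np.zeros((2, 5)))


class TestDirectionHistogram:
    def test_step_edge_single_bin(self):
        px = np.zeros((40, 40, 3), np.uint8)
        px[:, 20:] = 255
        hist = direction_histogram(compute_gradients(px), magnitude_floor_quantile=0.0)
        assert np.argmax(hist.counts) == 0
        assert hist.counts[0] > 0.99 * hist.total_mass

    def test_fold_conserves_mass(self, rng):
        g = compute_gradients(rng.uniform(0, 255, (30, 30)))
        hist = direction_histogram(g, magnitude_floor_quantile=0.75)
        mag = g.magnitude
        floor = np.quantile(mag[mag > 0], 0.75)
        expected = mag[mag >= floor].sum()
        assert np.isclose(hist.total_mass, expected, rtol=1e-9)

    def test_bad_bin_width_rejected(self, rng):
        g = compute_gradients(rng.uniform(0, 255, (10, 10)))
        with pytest.raises(ValueError):
            direction_histogram(g, bin_width_deg=7.0)

    def test_zero_field_raises(self):
        g = compute_gradients(np.full((10, 10, 3), 7, np.uint8))
        with pytest.raises(ValueError, match="rotation cannot be estimated"):
            direction_histogram(g)

    def test_grid_dominant_bin(self, clean_slide):
        img, _ = clean_slide
        hist = direction_histogram(compute_gradients(img))
        assert np.argmax(hist.counts) == 0
        assert hist.counts[0] > 0.5 * hist.total_mass


class TestEstimateAngle:
    @pytest.mark.parametrize(
        "peak_deg,expected",
        [(0, 0.0), (10, -10.0), (45, 45.0), (60, 30.0), (89, 1.0)],
    )
    def test_minimum_angle_rule(self, peak_deg, expected):
        counts = np.zeros(90)
        counts[peak_deg] = 100.0
        est = estimate_rotation_angle(DirectionHistogram(counts=counts, bin_width=1.0))
        assert est.angle_deg == pytest.approx(expected, abs=1e-9)
        assert est.reliable

    def test_flat_histogram_flagged_not_raised(self):
        est = estimate_rotation_angle(DirectionHistogram(counts=np.ones(90), bin_width=1.0))
        assert not est.reliable

    def test_brightness_scaling_invariance(self, clean_slide):
        img, _ = clean_slide
        dim = SlideImage(pixels=(img.pixels * 0.5).astype(np.uint8))
        a = estimate_rotation(img).angle_deg
        b = estimate_rotation(dim).angle_deg
        assert abs(a - b) <= 0.2


class TestRotationRecovery:
    @pytest.mark.parametrize("theta", [-35.0, -12.5, -1.5, 4.0, 23.5, 40.0])
    def test_recovers_generator_angle(self, theta):
        spec = SlidePhantomSpec(rotation_deg=theta, noise_sigma=0.0, class_labels=[3] * 12, seed=5)
        img, _ = generate_slide(spec)
        est = estimate_rotation(img)
        assert abs(est.angle_deg - (-theta)) <= 1.0

    def test_rotate_by_zero_is_identity(self, clean_slide):
        img, _ = clean_slide
        out = rotate_image(img.pixels, 0.0)
        assert np.array_equal(out, img.pixels)

    def test_normalize_cancels_generator_rotation(self):
        spec = SlidePhantomSpec(rotation_deg=10.0, class_labels=[3] * 12, seed=5)
        img, _ = generate_slide(spec)
        est = estimate_rotation(img)
        fixed = normalize_rotation(img, est)
        assert abs(estimate_rotation(fixed).angle_deg) <= 0.5

    def test_rotation_roundtrip_center_region(self, clean_slide):
        img, _ = clean_slide
        back = rotate_image(rotate_image(img.pixels, 30.0), -30.0)
        h, w = img.pixels.shape[:2]
        sl = (slice(h // 4, 3 * h // 4), slice(w // 4, 3 * w // 4))
        diff = np.abs(back[sl].astype(float) - img.pixels[sl].astype(float))
        assert diff.mean() < 10.0


class TestRotatePoints:
    def test_matches_image_rotation_of_a_dot(self):
        px = np.zeros((101, 151, 3), np.uint8)
        px[30, 120] = 255
        rot = rotate_image(px, 25.0, fill=np.zeros(3))
        r, c, _ = np.unravel_index(np.argmax(rot), rot.shape)
        (x, y), = rotate_points([[120, 30]], 25.0, (101, 151))
        assert abs(x - c) <= 1.0 and abs(y - r) <= 1.0

    def test_inverse_composition(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        fwd = rotate_points(pts, 33.0, (120, 130))
        back = rotate_points(fwd, -33.0, (120, 130))
        np.testing.assert_allclose(back, pts, atol=1e-9)
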