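"""Projection profiles, peak pairing and end-to-end intersection detection."""

import numpy as np
import pytest

from mycoquant import (
    GridLine,
    RunConfig,
    SlideImage,
    SlidePhantomSpec,
    compute_gradients,
    detect_edge_peaks,
    detect_intersections,
    generate_slide,
    intersections_from_lines,
    iou,
    match_detections,
    pair_edges_to_lines,
    projection_profiles,
)
from mycoquant.grid import ProjectionProfile


def _greedy_peaks_oracle(values, min_distance):
    """Highest-first suppression, written as an explicit loop."""
    values = np.asarray(values, float)
    is_max = [
        0 < i < len(values) - 1 and values[i - 1] < values[i] >= values[i + 1]
        for i in range(len(values))
    ]
    candidates = sorted((i for i in range(len(values)) if is_max[i]), key=lambda i: -values[i])
    kept = []
    for i in candidates:
        if all(abs(i - j) >= min_distance for j in kept):
            kept.append(i)
    return sorted(kept)


class TestProfiles:
    def test_zero_field_zero_profiles(self):
        g = compute_gradients(np.full((30, 30, 3), 50, np.uint8))
        pv, ph = projection_profiles(g)
        assert np.all(pv.values == 0) and np.all(ph.values == 0)

    def test_stripe_has_two_edge_maxima(self):
        px = np.full((40, 60, 3), 255, np.uint8)
        px[:, 30:34] = 0  # 4 px: wide enough that the 3x3 edge responses separate
        g = compute_gradients(px)
        pv, _ = projection_profiles(g)
        # loop-sum oracle for the column profile
        expected = np.abs(g.gx).sum(axis=0)
        np.testing.assert_allclose(pv.values, expected)
        peaks = detect_edge_peaks(pv, 1)
        assert len(peaks) == 2 and 28 <= peaks[0] <= 31 and 32 <= peaks[1] <= 35

    def test_grid_slide_has_six_vertical_peaks(self, clean_slide):
        img, gt = clean_slide
        pv, _ = projection_profiles(compute_gradients(img), smoothing_sigma=3.0)
        peaks = detect_edge_peaks(pv, 50)
        heights = pv.values[peaks]
        strong = peaks[heights >= 0.25 * heights.max()]
        assert len(strong) == 2 * len(gt.v_centers)


class TestPeakDetection:
    def test_worked_example(self):
        peaks = detect_edge_peaks(np.array([0, 0, 5, 0, 0, 9, 0, 0], float), 2)
        assert peaks.tolist() == [2, 5]

    def test_close_peaks_taller_wins(self):
        values = np.zeros(100)
        values[40] = 5.0
        values[50] = 9.0
        peaks = detect_edge_peaks(values, 50)
        assert peaks.tolist() == [50]

    def test_monotone_ramp_no_peaks(self):
        assert detect_edge_peaks(np.arange(100, dtype=float), 5).size == 0

    def test_constant_profile_empty(self):
        assert detect_edge_peaks(np.ones(50), 5).size == 0

    @pytest.mark.parametrize("distance", [1, 3, 10, 50])
    def test_matches_greedy_oracle_on_random_profiles(self, distance, rng):
        for _ in range(20):
            values = rng.uniform(0, 10, 200)
            got = detect_edge_peaks(values, distance).tolist()
            assert got == _greedy_peaks_oracle(values, distance)


class TestPairing:
    def test_two_clean_pairs(self):
        lines = pair_edges_to_lines([100, 110, 300, 310], 30)
        assert [l.center for l in lines] == [105.0, 305.0]
        assert all(not l.single_edge for l in lines)

    def test_greedy_no_reuse(self):
        lines = pair_edges_to_lines([100, 110, 118], 30)
        assert [l.center for l in lines] == [105.0, 118.0]
        assert [l.single_edge for l in lines] == [False, True]

    def test_lone_peak_single_edge_line(self):
        (line,) = pair_edges_to_lines([100], 30)
        assert line.center == 100.0 and line.single_edge

    def test_single_edge_placed_by_polarity(self):
        # negative polarity: intensity drops left-to-right, line lies to the right
        (line,) = pair_edges_to_lines([100], 30, polarities=[-1.0], nominal_width=20)
        assert line.center == 110.0 and line.width == 20.0
        (line,) = pair_edges_to_lines([100], 30, polarities=[+1.0], nominal_width=20)
        assert line.center == 90.0

    def test_singletons_dropped_when_disabled(self):
        lines = pair_edges_to_lines([100, 110, 300], 30, keep_single_edges=False)
        assert [l.center for l in lines] == [105.0]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            pair_edges_to_lines([110, 100], 30)


class TestIntersections:
    def test_cartesian_product(self):
        h = [GridLine("horizontal", 195, 205), GridLine("horizontal", 495, 505)]
        v = [GridLine("vertical", x - 5, x + 5) for x in (200, 500, 800)]
        boxes = intersections_from_lines(h, v, (756, 1008), box_half_extent=75)
        assert len(boxes) == len(h) * len(v)

    def test_border_box_dropped_below_half_area(self):
        h = [GridLine("horizontal", 5, 15)]
        v = [GridLine("vertical", 5, 15)]
        # crossing at (10, 10): a 150x150 box keeps 85x85 < 50% of nominal
        assert intersections_from_lines(h, v, (756, 1008), 75) == []
        # with half-extent 20 the clipped 30x30 keeps 56% and survives
        assert len(intersections_from_lines(h, v, (756, 1008), 20)) == 1

    def test_no_vertical_lines_no_boxes(self):
        h = [GridLine("horizontal", 195, 205)]
        assert intersections_from_lines(h, [], (756, 1008)) == []


class TestDetectIntersections:
    def test_clean_aligned_slide_recovers_all_crossings(self, clean_slide):
        img, gt = clean_slide
        result = detect_intersections(img)
        assert len(result.boxes) == len(gt.boxes) == 9
        rep = match_detections(gt.boxes, result.boxes)
        assert all(v >= 0.9 for v in rep.matched_ious)

    def test_rotated_slide_recovered_after_normalization(self):
        spec = SlidePhantomSpec(
            width_px=756, height_px=756, grid_spacing_px=252, rotation_deg=15.0,
            noise_sigma=0.0, class_labels=[3] * 9, seed=11,
        )
        img, gt = generate_slide(spec)
        result = detect_intersections(img)
        rep = match_detections(gt.boxes, result.boxes)
        assert rep.n_gt == len(rep.pairs)
        assert all(v >= 0.8 for v in rep.matched_ious)

    def test_blank_image_zero_boxes(self):
        img = SlideImage(pixels=np.full((400, 400, 3), 255, np.uint8))
        result = detect_intersections(img)
        assert result.boxes == []

    def test_deterministic_byte_for_byte(self, clean_slide):
        img, _ = clean_slide
        a = detect_intersections(img)
        b = detect_intersections(img)
        assert a.boxes == b.boxes
        assert a.rotation.angle_deg == b.rotation.angle_deg

    def test_quarter_turn_equivariance(self, clean_slide):
        img, _ = clean_slide
        turned = SlideImage(pixels=np.ascontiguousarray(np.rot90(img.pixels)))
        base = detect_intersections(img)
        rot = detect_intersections(turned)
        h = img.pixels.shape[0]
        # np.rot90 maps (x, y) -> (y, h - 1 - x); box corners follow suit
        mapped = {
            (b.y0, h - b.x1, b.y1, h - b.x0) for b in base.boxes
        }
        got = {(b.x0, b.y0, b.x1, b.y1) for b in rot.boxes}
        # centers must coincide within rounding of the detected line positions
        assert len(got) == len(mapped)
        for bx in got:
            assert any(all(abs(a - b) <= 2 for a, b in zip(bx, m)) for m in mapped)
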