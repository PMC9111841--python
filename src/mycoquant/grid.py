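"""Grid-line and intersection detection on deskewed slides.

On an axis-aligned grid the two edges of every line show up as peaks of
the projection profiles: the column-wise sum of |d/dx| for vertical
lines and the row-wise sum of |d/dy| for horizontal lines.  Peaks are
paired into lines (a line's two edges are much closer together than
neighboring lines are), and the Cartesian product of horizontal and
vertical line centers gives the grid crossings, each of which becomes a
square sampling-area box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core import IntersectionBox, RunConfig, SlideImage, box_around
from .rotation import (
    GradientField,
    RotationEstimate,
    compute_gradients,
    estimate_rotation,
    normalize_rotation,
    rotate_points,
)

log = logging.getLogger(__name__)


@dataclass
class ProjectionProfile:
    """1-D profile of summed gradient magnitude along one axis.

    ``axis`` names the grid-line orientation the profile detects:
    ``"vertical"`` profiles are per-column sums of |gx| (length = image
    width), ``"horizontal"`` ones per-row sums of |gy|.  ``signed``
    keeps the sum of the signed derivative, used to tell which side of
    a lone edge the line lies on.
    """

    axis: str
    values: np.ndarray
    signed: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.axis not in ("horizontal", "vertical"):
            raise ValueError(f"axis must be horizontal|vertical, got {self.axis!r}")
        self.values = np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class GridLine:
    """One grid line, described by its two edge positions along the profile axis."""

    orientation: str  # "horizontal" | "vertical"
    edge_lo: float
    edge_hi: float
    single_edge: bool = False

    def __post_init__(self) -> None:
        if self.edge_hi <= self.edge_lo:
            raise ValueError("edge_hi must exceed edge_lo")

    @property
    def center(self) -> float:
        return (self.edge_lo + self.edge_hi) / 2.0

    @property
    def width(self) -> float:
        return self.edge_hi - self.edge_lo


@dataclass
class DetectionResult:
    """Detected boxes plus the diagnostics that produced them.

    ``boxes`` are in the coordinates of the *input* image; when a
    rotation correction was applied, ``boxes_normalized`` holds the
    boxes in the deskewed frame together with the estimate used.
    """

    boxes: list[IntersectionBox]
    h_lines: list[GridLine]
    v_lines: list[GridLine]
    rotation: Optional[RotationEstimate] = None
    boxes_normalized: Optional[list[IntersectionBox]] = None  # index-aligned with boxes
    normalized: Optional[SlideImage] = None  # the deskewed image the boxes came from
    profiles: Optional[tuple[ProjectionProfile, ProjectionProfile]] = None


def projection_profiles(
    grad: GradientField, smoothing_sigma: float = 0.0
) -> tuple[ProjectionProfile, ProjectionProfile]:
    """(vertical-line, horizontal-line) profiles from a gradient field."""
    col = np.abs(grad.gx).sum(axis=0)
    row = np.abs(grad.gy).sum(axis=1)
    col_signed = grad.gx.sum(axis=0)
    row_signed = grad.gy.sum(axis=1)
    if smoothing_sigma > 0:
        col = gaussian_filter1d(col, smoothing_sigma)
        row = gaussian_filter1d(row, smoothing_sigma)
        col_signed = gaussian_filter1d(col_signed, smoothing_sigma)
        row_signed = gaussian_filter1d(row_signed, smoothing_sigma)
    return (
        ProjectionProfile(axis="vertical", values=col, signed=col_signed),
        ProjectionProfile(axis="horizontal", values=row, signed=row_signed),
    )


def detect_edge_peaks(profile: ProjectionProfile | np.ndarray, min_distance: int) -> np.ndarray:
    """Local maxima of a profile under highest-first distance suppression.

    Peaks closer than ``min_distance`` to a taller peak are discarded;
    positions are returned sorted ascending.
    """
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    values = profile.values if isinstance(profile, ProjectionProfile) else np.asarray(profile, float)
    if len(values) < 3 or np.allclose(values, values[0]):
        return np.array([], dtype=int)
    peaks, _ = find_peaks(values, distance=min_distance)
    return peaks


def _split_threshold(peaks: np.ndarray, fallback: float) -> float:
    """Adaptive edge-pair / line-spacing gap split.

    Consecutive-peak gaps cluster at the line width w and at the
    inter-line gap (roughly 3w on a grid with a 1:4 width:pitch ratio).
    The threshold is placed at the largest multiplicative jump in the
    sorted gaps; if the gaps form a single cluster they are all line
    spacings (every line contributed one surviving edge) and nothing is
    paired.
    """
    gaps = np.diff(np.asarray(peaks, dtype=float))
    if len(gaps) < 2:
        return fallback
    g = np.sort(gaps)
    ratios = g[1:] / np.maximum(g[:-1], 1e-9)
    j = int(np.argmax(ratios))
    if ratios[j] < 1.5:
        return 0.0  # single cluster: no edge pairs
    return float(np.sqrt(g[j] * g[j + 1]))


def pair_edges_to_lines(
    peaks: Sequence[float] | np.ndarray,
    max_line_width_px: float,
    orientation: str = "vertical",
    polarities: Optional[Sequence[float]] = None,
    nominal_width: Optional[float] = None,
    keep_single_edges: bool = True,
    line_polarity: str = "dark",
) -> list[GridLine]:
    """Greedy left-to-right pairing of edge peaks into grid lines.

    Consecutive peaks no farther apart than ``max_line_width_px`` form
    one line; no peak is used twice.  When edge polarities (the sign of
    the summed signed derivative at each peak) are supplied, a pair
    must additionally bracket a line body: with ``line_polarity="dark"``
    (lines darker than the field, as for an orange grid on a pale
    slide) that means a falling then a rising edge.  This rejects
    spurious pairings of edges that belong to *different* lines.  A
    leftover lone peak is kept as a single-edge line of
    ``nominal_width``, placed on the line side its polarity indicates
    (centered on the peak when the polarity is unknown).
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size == 0:
        return []
    if np.any(np.diff(peaks) < 0):
        raise ValueError("peaks must be sorted ascending")
    if line_polarity not in ("dark", "bright"):
        raise ValueError("line_polarity must be 'dark' or 'bright'")
    pol = None if polarities is None else np.sign(np.asarray(polarities, dtype=float))
    dark_first = 1.0 if line_polarity == "dark" else -1.0
    lines: list[GridLine] = []
    i = 0
    n = len(peaks)
    while i < n:
        if i + 1 < n and peaks[i + 1] - peaks[i] <= max_line_width_px:
            ok = True
            if pol is not None and pol[i] != 0 and pol[i + 1] != 0:
                ok = pol[i] * dark_first < 0 and pol[i + 1] * dark_first > 0
            if ok:
                lines.append(GridLine(orientation, float(peaks[i]), float(peaks[i + 1])))
                i += 2
                continue
        if keep_single_edges:
            p = float(peaks[i])
            offset = 0.0
            if nominal_width:
                w = float(nominal_width)
                if pol is not None and pol[i] != 0:
                    # a falling edge (for dark lines: negative derivative)
                    # means the line body lies to the right of this peak
                    s = pol[i] * dark_first
                    offset = w / 2.0 if s < 0 else -w / 2.0
            else:
                # width unknown: keep the line centered on its edge peak
                w = max(float(max_line_width_px), 2.0)
            c = p + offset
            lines.append(GridLine(orientation, c - w / 2.0, c + w / 2.0, single_edge=True))
        i += 1
    return lines


def intersections_from_lines(
    h_lines: Sequence[GridLine],
    v_lines: Sequence[GridLine],
    image_shape_hw: tuple[int, int],
    box_half_extent: int = 75,
    min_clipped_area_frac: float = 0.5,
) -> list[IntersectionBox]:
    """One sampling-area box per (horizontal, vertical) line crossing.

    Boxes are squares of side ``2 * box_half_extent`` centered on the
    crossing, clipped to the image; a box that keeps less than
    ``min_clipped_area_frac`` of its nominal area is dropped.
    """
    h, w = image_shape_hw
    nominal = (2 * box_half_extent) ** 2
    boxes: list[IntersectionBox] = []
    for hl in h_lines:
        for vl in v_lines:
            box = box_around(vl.center, hl.center, box_half_extent)
            clipped = box.clipped(w, h)
            if clipped is None or clipped.area < min_clipped_area_frac * nominal:
                continue
            boxes.append(clipped)
    return boxes


def _search_single_edge_width(
    single_pos: np.ndarray,
    single_dir: np.ndarray,
    fixed_centers: np.ndarray,
    ratio: float,
    pair_widths: Sequence[float] = (),
) -> float:
    """Line width that makes polarity-placed single edges fall on a lattice.

    Candidate widths shift each lone edge onto its line center
    (``pos + dir * w / 2``); the width that makes the resulting center
    sequence most evenly pitched wins.  When the score is flat in w —
    all surviving edges sit on the same side of their lines, so a
    common shift cannot be detected — the physical width/pitch ratio
    applied to the raw pitch is used instead.
    """

    def centers_at(w: float) -> np.ndarray:
        return np.sort(np.concatenate([fixed_centers, single_pos + single_dir * (w / 2.0)]))

    def spread(w: float) -> float:
        d = np.diff(centers_at(w))
        if len(d) == 0:
            return 0.0
        return float(np.median(np.abs(d - np.median(d))))

    base_diffs = np.diff(centers_at(0.0))
    base = float(np.median(base_diffs)) if len(base_diffs) else 0.0
    fallback = max(ratio * base, 2.0)
    if pair_widths:
        fallback = float(np.median(pair_widths))
    if base <= 4 or len(single_pos) + len(fixed_centers) < 3 or not np.any(single_dir != 0):
        return fallback
    candidates = np.concatenate([np.arange(2.0, 0.6 * base, 0.5), np.asarray(pair_widths, float)])
    scores = np.array([spread(w) for w in candidates])
    best = int(np.argmin(scores))
    if scores[best] < 0.8 * spread(fallback):
        return float(candidates[best])
    return fallback


def _lattice_inlier_mask(centers: np.ndarray, pitch: float, tol_frac: float = 0.15) -> np.ndarray:
    """Mark lines consistent with an evenly pitched lattice.

    Each line in turn anchors the lattice; the anchor whose lattice
    explains the most lines wins.  Lines farther than ``tol_frac *
    pitch`` from that lattice are spurious (e.g. aggregated root-edge
    or bubble-rim projections).
    """
    best = np.zeros(len(centers), dtype=bool)
    for anchor in centers:
        resid = np.abs((centers - anchor + pitch / 2.0) % pitch - pitch / 2.0)
        inliers = resid <= tol_frac * pitch
        if inliers.sum() > best.sum():
            best = inliers
    return best


def _refine_on_luminance(
    lines: list[GridLine],
    lum_mean: np.ndarray,
    pitch: float,
    orientation: str,
) -> list[GridLine]:
    """Re-center each line on the luminance dip it produces.

    Grid lines are darker than the surrounding field, so the mean
    luminance along the line's axis dips over the line body.  The
    centroid of that dip inside a window around the detected position
    relocates the center — independent of which of the line's two
    edges survived peak suppression — and the dip's half-maximum run
    re-measures the width.  Lines that converge onto the same dip are
    merged.
    """
    bg = float(np.median(lum_mean))
    # squared dip: the deep dip of the line body dominates the shallow
    # dips of overlying root tissue
    dip = np.clip(bg - lum_mean, 0.0, None) ** 2
    n = len(lum_mean)
    lines = _merge_close(sorted(lines, key=lambda l: l.center), 0.4 * pitch, orientation)
    refined: list[GridLine] = []
    for l in lines:
        half = max(pitch / 3.0, l.width)
        a = max(int(l.center - half), 0)
        b = min(int(l.center + half) + 1, n)
        w = dip[a:b]
        if w.sum() <= 0:
            refined.append(l)
            continue
        centroid = a + float((w * np.arange(len(w))).sum() / w.sum())
        thr = 0.5 * w.max()
        mask = w >= thr
        ci = min(max(int(round(centroid)) - a, 0), len(w) - 1)
        lo = hi = ci
        while lo > 0 and mask[lo - 1]:
            lo -= 1
        while hi < len(w) - 1 and mask[hi + 1]:
            hi += 1
        width = max(hi - lo + 1.0, 2.0)
        refined.append(
            GridLine(orientation, centroid - width / 2.0, centroid + width / 2.0, l.single_edge)
        )
    refined.sort(key=lambda l: l.center)
    return _merge_close(refined, 0.4 * pitch, orientation)


def _merge_close(sorted_lines: list[GridLine], min_sep: float, orientation: str) -> list[GridLine]:
    """Collapse lines closer than ``min_sep`` (duplicates of one line)."""
    merged: list[GridLine] = []
    for l in sorted_lines:
        if merged and abs(l.center - merged[-1].center) < min_sep:
            keep = merged[-1]
            c = (keep.center + l.center) / 2.0
            width = (keep.width + l.width) / 2.0
            merged[-1] = GridLine(
                orientation, c - width / 2.0, c + width / 2.0, keep.single_edge and l.single_edge
            )
            continue
        merged.append(l)
    return merged


def _lines_from_profile(
    profile: ProjectionProfile,
    config: RunConfig,
    orientation: str,
    lum_mean: Optional[np.ndarray] = None,
) -> list[GridLine]:
    peaks = detect_edge_peaks(profile, config.peak_distance)
    log.info("%s profile: %d edge peaks", orientation, len(peaks))
    if peaks.size == 0:
        return []
    if config.min_peak_rel_height > 0:
        # a grid-line edge projects over the whole image extent; bumps
        # from root texture or noise are far below the tallest peak
        heights = profile.values[peaks]
        keep = heights >= config.min_peak_rel_height * heights.max()
        peaks = peaks[keep]
        log.info("%s: %d peaks above relative-height floor", orientation, len(peaks))
    threshold = (
        float(config.max_line_width_px)
        if config.max_line_width_px is not None
        else _split_threshold(peaks, fallback=2.0 * config.peak_distance)
    )
    polarities = profile.signed[peaks] if profile.signed is not None else None
    # pass 1: polarity-aware pairing, lone edges provisionally centered
    # on their peaks; this yields the paired widths (or the lattice)
    # from which the true line width of lone edges is estimated
    lines = pair_edges_to_lines(
        peaks,
        threshold,
        orientation,
        polarities=polarities,
        keep_single_edges=config.keep_single_edges,
    )
    singles = [l for l in lines if l.single_edge]
    paired_widths = [l.width for l in lines if not l.single_edge]
    nominal = float(np.median(paired_widths)) if paired_widths else None
    if singles:
        pol_sign = np.sign(polarities) if polarities is not None else np.zeros(len(peaks))
        single_mask = np.array([any(abs(l.center - p) < 0.5 for l in singles) for p in peaks])
        dirs = np.where(
            pol_sign[single_mask] < 0, 1.0, np.where(pol_sign[single_mask] > 0, -1.0, 0.0)
        )
        nominal = _search_single_edge_width(
            peaks[single_mask].astype(float),
            dirs,
            np.array([l.center for l in lines if not l.single_edge]),
            config.line_spacing_ratio,
            pair_widths=paired_widths,
        )
        lines = pair_edges_to_lines(
            peaks,
            threshold,
            orientation,
            polarities=polarities,
            nominal_width=nominal,
            keep_single_edges=config.keep_single_edges,
        )
    if nominal is not None and config.keep_single_edges:
        # a "pair" much wider than the consensus line width joined a
        # genuine edge with a spurious peak: split it back into
        # polarity-placed single edges and let the lattice filter sort
        # the impostor out
        rebuilt: list[GridLine] = []
        pol_at = {float(p): float(np.sign(profile.signed[p])) if profile.signed is not None else 0.0 for p in peaks}
        for l in lines:
            if l.single_edge or l.width <= 1.5 * nominal:
                rebuilt.append(l)
                continue
            for edge in (l.edge_lo, l.edge_hi):
                s = pol_at.get(float(edge), 0.0)
                offset = nominal / 2.0 if s < 0 else (-nominal / 2.0 if s > 0 else 0.0)
                c = edge + offset
                rebuilt.append(
                    GridLine(orientation, c - nominal / 2.0, c + nominal / 2.0, single_edge=True)
                )
        if len(rebuilt) != len(lines):
            rebuilt.sort(key=lambda l: l.center)
            lines = rebuilt
    if lum_mean is not None and len(lines) >= 1:
        if len(lines) >= 2:
            pitch = float(np.median(np.diff([l.center for l in lines])))
        else:
            pitch = 2.0 * config.peak_distance
        lines = _refine_on_luminance(lines, lum_mean, max(pitch, 8.0), orientation)
    # drop lines that break the even grid pitch (spurious projections)
    if len(lines) >= 4:
        centers = np.array([l.center for l in lines])
        pitch = float(np.median(np.diff(centers)))
        if pitch > 4:
            inliers = _lattice_inlier_mask(centers, pitch)
            if 3 <= inliers.sum() < len(lines):
                log.info("%s: dropping %d off-lattice lines", orientation, int((~inliers).sum()))
                lines = [l for l, k in zip(lines, inliers) if k]
    log.info(
        "%s: %d lines (%d single-edge)", orientation, len(lines), sum(l.single_edge for l in lines)
    )
    return lines


def detect_intersections(image: SlideImage, config: Optional[RunConfig] = None) -> DetectionResult:
    """Full detection pipeline: deskew, profile, pair, intersect.

    Returns boxes in the input image's coordinate frame; zero boxes is
    a valid (logged) outcome.  Deterministic for fixed input + config.
    """
    config = config or RunConfig()
    try:
        est = estimate_rotation(
            image,
            bin_width_deg=config.bin_width_deg,
            magnitude_floor_quantile=config.magnitude_floor_quantile,
            presmooth_sigma=config.rotation_presmooth_sigma,
        )
    except ValueError:
        log.warning("%s: no usable gradients; skipping deskew", image.source_id)
        est = RotationEstimate(angle_deg=0.0, confidence=0.0, reliable=False)
    if est.reliable and abs(est.angle_deg) > 1e-6:
        normalized = normalize_rotation(image, est, expand=config.expand_canvas)
    else:
        normalized = image
    grad = compute_gradients(normalized)
    prof_v, prof_h = projection_profiles(grad, config.smoothing_sigma)
    from .rotation import luminance

    lum = luminance(normalized.pixels)
    v_lines = _lines_from_profile(prof_v, config, "vertical", lum_mean=lum.mean(axis=0))
    h_lines = _lines_from_profile(prof_h, config, "horizontal", lum_mean=lum.mean(axis=1))
    norm_shape = normalized.pixels.shape[:2]
    boxes_norm = intersections_from_lines(
        h_lines, v_lines, norm_shape, config.box_half_extent, config.min_clipped_area_frac
    )
    log.info(
        "%s: %d h-lines x %d v-lines -> %d boxes",
        image.source_id,
        len(h_lines),
        len(v_lines),
        len(boxes_norm),
    )
    if est.reliable and abs(est.angle_deg) > 1e-6 and not config.expand_canvas:
        # map centers back into the un-deskewed input frame, keeping
        # the original-frame and deskewed-frame box lists index-aligned
        centers = np.array([b.center for b in boxes_norm]).reshape(-1, 2)
        back = rotate_points(centers, -est.angle_deg, norm_shape)
        boxes: list[IntersectionBox] = []
        kept_norm: list[IntersectionBox] = []
        nominal = (2 * config.box_half_extent) ** 2
        for bn, (cx, cy) in zip(boxes_norm, back):
            b = box_around(cx, cy, config.box_half_extent).clipped(
                image.width_px, image.height_px
            )
            if b is not None and b.area >= config.min_clipped_area_frac * nominal:
                boxes.append(b)
                kept_norm.append(bn)
        boxes_norm = kept_norm
    else:
        boxes = list(boxes_norm)
    return DetectionResult(
        boxes=boxes,
        h_lines=h_lines,
        v_lines=v_lines,
        rotation=est,
        boxes_normalized=boxes_norm,
        normalized=normalized,
        profiles=(prof_v, prof_h),
    )


def extract_sampling_areas(image: SlideImage, result: DetectionResult):
    """Crop each detected box out of the slide as a square SamplingArea.

    Patches are cropped from the deskewed frame (so the grid cross is
    axis-aligned, matching how training patches are oriented) while
    ``source_box`` stays in the input image's coordinates.
    """
    from .core import SamplingArea

    if result.normalized is not None and result.boxes_normalized is not None:
        pixels = result.normalized.pixels
        crop_boxes = result.boxes_normalized
    else:
        pixels = image.pixels
        crop_boxes = result.boxes
    areas = []
    for box, crop_box in zip(result.boxes, crop_boxes):
        patch = crop_box.crop(pixels)
        side = min(patch.shape[0], patch.shape[1])
        patch = patch[:side, :side]
        if side < 8:
            continue
        areas.append(SamplingArea(patch=patch, source_box=box))
    return areas
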