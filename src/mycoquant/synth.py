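"""Synthetic slide phantoms with exact ground truth.

Real gridded-slide photographs of stained roots are not distributed
with the package, so tests and demos run on rendered phantoms: a pale
slide background, an orthogonal orange grid of known pitch and width
(width = 0.25 x pitch by default, matching 0.25 mm lines on a 1.00 mm
grid), blue-gray root patches carrying class-distinctive dark
structures at the crossings, optional air-bubble and jagged-edge
artifacts, Gaussian pixel noise, and finally a known whole-scene
rotation.  The renderer records the true line centers, crossing boxes
and per-crossing class labels, transformed through the same rotation
applied to the pixels.

The class morphologies are deliberate caricatures (blobs for vesicles,
filament skeletons for arbuscules): separable by construction, adequate
for exercising the pipeline, and not a claim about real micrographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.draw import disk, ellipse, circle_perimeter

from .core import ClassLabel, IntersectionBox, SamplingArea, SlideImage, box_around
from .rotation import rotate_image, rotate_points

ORANGE = (230, 140, 40)
BACKGROUND = (238, 234, 226)
ROOT_COLOR = (150, 155, 182)  # desaturated blue-gray, trypan-blue-ish tissue
STRUCTURE_COLOR = (42, 48, 98)  # dark stained fungal structures


@dataclass
class SlidePhantomSpec:
    """Rendering parameters for one phantom slide."""

    width_px: int = 1008
    height_px: int = 756
    rotation_deg: float = 0.0
    grid_spacing_px: int = 252
    line_width_px: Optional[int] = None  # default 0.25 x spacing
    line_color: tuple[int, int, int] = ORANGE
    background_color: tuple[int, int, int] = BACKGROUND
    class_labels: Optional[Sequence[int]] = None  # per-crossing; random when None
    n_bubbles: int = 0
    bubble_radius_px: tuple[int, int] = (18, 45)
    jag_amplitude_px: float = 0.0
    noise_sigma: float = 2.0
    box_half_extent: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.line_width_px is None:
            self.line_width_px = max(2, int(round(0.25 * self.grid_spacing_px)))
        if self.line_width_px >= self.grid_spacing_px:
            raise ValueError(
                f"line width {self.line_width_px} must be narrower than the "
                f"grid spacing {self.grid_spacing_px}"
            )
        if self.grid_spacing_px > min(self.width_px, self.height_px):
            raise ValueError("grid spacing exceeds the image extent: no lines would fit")
        if abs(self.rotation_deg) > 45:
            raise ValueError("|rotation_deg| must be <= 45")


@dataclass
class SlideGroundTruth:
    """Exact geometry and labels of a rendered phantom."""

    rotation_deg: float
    h_centers: np.ndarray  # horizontal-line y centers, pre-rotation frame
    v_centers: np.ndarray  # vertical-line x centers, pre-rotation frame
    boxes: list[IntersectionBox]  # in the final (rotated) frame
    labels: list[ClassLabel]


def _line_centers(extent: int, spacing: int) -> np.ndarray:
    """Evenly pitched line centers, symmetric about the image center."""
    n = extent // spacing
    offset = (extent - (n - 1) * spacing) / 2.0
    return offset + spacing * np.arange(n)


def _draw_root_patch(img: np.ndarray, cx: float, cy: float, label: ClassLabel, rng: np.random.Generator) -> None:
    """Blue-gray root tissue around a crossing plus class-specific structures."""
    h, w = img.shape[:2]
    if label == ClassLabel.NO_ROOT:
        return
    ry = rng.uniform(45, 70)
    rx = rng.uniform(70, 100)
    ang = rng.uniform(0, np.pi)
    rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=ang)
    tint = np.array(ROOT_COLOR, float) + rng.normal(0, 4, 3)
    img[rr, cc] = 0.25 * img[rr, cc] + 0.75 * tint
    if label == ClassLabel.VESICLES:
        for _ in range(int(rng.integers(3, 7))):
            vr = rng.uniform(7, 13)
            vx = cx + rng.uniform(-rx * 0.6, rx * 0.6)
            vy = cy + rng.uniform(-ry * 0.6, ry * 0.6)
            rr, cc = disk((vy, vx), vr, shape=(h, w))
            img[rr, cc] = STRUCTURE_COLOR
    elif label == ClassLabel.ARBUSCULES:
        for _ in range(int(rng.integers(8, 15))):
            x, y = cx + rng.uniform(-rx * 0.5, rx * 0.5), cy + rng.uniform(-ry * 0.5, ry * 0.5)
            direction = rng.uniform(0, 2 * np.pi)
            for _step in range(int(rng.integers(15, 40))):
                direction += rng.normal(0, 0.45)
                x += 2.0 * np.cos(direction)
                y += 2.0 * np.sin(direction)
                xi, yi = int(round(x)), int(round(y))
                if 0 <= xi < w - 1 and 0 <= yi < h - 1:
                    img[yi : yi + 2, xi : xi + 2] = STRUCTURE_COLOR


def _jagged_offsets(n: int, amp: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Edge perturbations for a degraded grid line.

    A smooth meander shared by both edges makes the whole line wander
    off its nominal position (so its projected center is biased), and
    independent high-frequency roughness per edge smears the projection
    peaks — together a caricature of worn, raggedly printed grid lines.
    """
    from scipy.ndimage import gaussian_filter1d

    wander = gaussian_filter1d(rng.normal(0.0, 1.0, n), 60, mode="nearest")
    sd = wander.std()
    if sd > 0:
        wander *= 0.6 * amp / sd
    rough_lo = rng.normal(0.0, 0.25 * amp, n)
    rough_hi = rng.normal(0.0, 0.25 * amp, n)
    return wander + rough_lo, wander + rough_hi


def _draw_grid(img: np.ndarray, v_centers: np.ndarray, h_centers: np.ndarray, spec: SlidePhantomSpec, rng: np.random.Generator) -> None:
    h, w = img.shape[:2]
    half = spec.line_width_px / 2.0
    color = np.array(spec.line_color, float)
    amp = spec.jag_amplitude_px
    for x in v_centers:
        lo = np.full(h, x - half)
        hi = np.full(h, x + half)
        if amp > 0:
            dlo, dhi = _jagged_offsets(h, amp, rng)
            lo += dlo
            hi += dhi
        for r in range(h):
            a, b = int(round(lo[r])), int(round(hi[r]))
            img[r, max(a, 0) : min(b, w)] = color
    for y in h_centers:
        lo = np.full(w, y - half)
        hi = np.full(w, y + half)
        if amp > 0:
            dlo, dhi = _jagged_offsets(w, amp, rng)
            lo += dlo
            hi += dhi
        for c in range(w):
            a, b = int(round(lo[c])), int(round(hi[c]))
            img[max(a, 0) : min(b, h), c] = color


def _draw_bubbles(img: np.ndarray, spec: SlidePhantomSpec, rng: np.random.Generator) -> None:
    """Air bubbles: faintly lightened disks with bright, high-gradient rims."""
    h, w = img.shape[:2]
    for _ in range(spec.n_bubbles):
        r = int(rng.integers(spec.bubble_radius_px[0], spec.bubble_radius_px[1] + 1))
        cy = int(rng.integers(r, h - r))
        cx = int(rng.integers(r, w - r))
        rr, cc = disk((cy, cx), r, shape=(h, w))
        img[rr, cc] = 0.85 * img[rr, cc] + 0.15 * 255.0
        for dr in range(3):
            rr, cc = circle_perimeter(cy, cx, r - dr, shape=(h, w))
            img[rr, cc] = (252, 252, 255)


def generate_slide(spec: SlidePhantomSpec) -> tuple[SlideImage, SlideGroundTruth]:
    """Render one phantom slide and its exact ground truth.

    Deterministic for a fixed spec (the seed drives every random
    element).  Ground-truth boxes at the image border are subject to
    the same >= 50%-area rule the detector applies.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    img = np.empty((h, w, 3), float)
    img[:] = spec.background_color
    img += rng.normal(0, 1.0, img.shape)

    v_centers = _line_centers(w, spec.grid_spacing_px)
    h_centers = _line_centers(h, spec.grid_spacing_px)
    crossings = [(x, y) for y in h_centers for x in v_centers]
    if spec.class_labels is not None:
        if len(spec.class_labels) != len(crossings):
            raise ValueError(
                f"{len(spec.class_labels)} labels supplied for {len(crossings)} crossings"
            )
        labels = [ClassLabel(int(l)) for l in spec.class_labels]
    else:
        labels = [ClassLabel(int(l)) for l in rng.integers(0, 4, len(crossings))]

    # the grid is etched into the slide; the stained root lies on top
    _draw_grid(img, v_centers, h_centers, spec, rng)
    for (x, y), lab in zip(crossings, labels):
        _draw_root_patch(img, x, y, lab, rng)
    if spec.n_bubbles:
        _draw_bubbles(img, spec, rng)
    if spec.noise_sigma > 0:
        img += rng.normal(0, spec.noise_sigma, img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)

    if spec.rotation_deg != 0.0:
        pixels = rotate_image(pixels, spec.rotation_deg, fill=np.array(spec.background_color, float))
        centers = rotate_points(np.array(crossings, float), spec.rotation_deg, (h, w))
    else:
        centers = np.array(crossings, float)

    boxes: list[IntersectionBox] = []
    kept_labels: list[ClassLabel] = []
    nominal = (2 * spec.box_half_extent) ** 2
    for (cx, cy), lab in zip(centers, labels):
        b = box_around(cx, cy, spec.box_half_extent).clipped(w, h)
        if b is None or b.area < 0.5 * nominal:
            continue
        boxes.append(b)
        kept_labels.append(lab)

    gt = SlideGroundTruth(
        rotation_deg=spec.rotation_deg,
        h_centers=h_centers,
        v_centers=v_centers,
        boxes=boxes,
        labels=kept_labels,
    )
    return SlideImage(pixels=pixels, source_id=f"phantom-seed{spec.seed}"), gt


# --------------------------------------------------------------------------
# classification patches


def _render_patch(label: ClassLabel, patch_px: int, rng: np.random.Generator) -> np.ndarray:
    """One sampling-area patch: grid cross + class-specific root content."""
    p = patch_px
    img = np.empty((p, p, 3), float)
    img[:] = BACKGROUND
    img += rng.normal(0, 1.0, img.shape)
    lw = max(2, int(round(0.25 * p)))
    cx = p / 2.0 + rng.uniform(-p * 0.04, p * 0.04)
    cy = p / 2.0 + rng.uniform(-p * 0.04, p * 0.04)
    color = np.array(ORANGE, float)
    img[:, int(cx - lw / 2) : int(cx + lw / 2)] = color
    img[int(cy - lw / 2) : int(cy + lw / 2), :] = color
    if label != ClassLabel.NO_ROOT:
        ang = rng.uniform(0, np.pi)
        rr, cc = ellipse(
            cy + rng.uniform(-5, 5),
            cx + rng.uniform(-5, 5),
            rng.uniform(0.22, 0.32) * p,
            rng.uniform(0.45, 0.6) * p,
            shape=(p, p),
            rotation=ang,
        )
        band = np.zeros((p, p), bool)
        band[rr, cc] = True
        tint = np.array(ROOT_COLOR, float) + rng.normal(0, 4, 3)
        img[band] = 0.2 * img[band] + 0.8 * tint
        ys, xs = np.nonzero(band)
        if label == ClassLabel.VESICLES:
            for _ in range(int(rng.integers(2, 6))):
                i = rng.integers(0, len(ys))
                rr, cc = disk((ys[i], xs[i]), rng.uniform(0.05, 0.09) * p, shape=(p, p))
                keep = band[rr, cc]
                img[rr[keep], cc[keep]] = STRUCTURE_COLOR
        elif label == ClassLabel.ARBUSCULES:
            for _ in range(int(rng.integers(6, 12))):
                i = rng.integers(0, len(ys))
                x, y = float(xs[i]), float(ys[i])
                direction = rng.uniform(0, 2 * np.pi)
                for _step in range(int(rng.integers(10, 30))):
                    direction += rng.normal(0, 0.5)
                    x += 1.6 * np.cos(direction)
                    y += 1.6 * np.sin(direction)
                    xi, yi = int(round(x)), int(round(y))
                    if 0 <= xi < p - 1 and 0 <= yi < p - 1 and band[yi, xi]:
                        img[yi : yi + 2, xi : xi + 2] = STRUCTURE_COLOR
    img += rng.normal(0, 2.5, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_classification_set(
    n_per_class: int, patch_px: int = 150, seed: int = 0
) -> list[SamplingArea]:
    """Balanced labeled patches, ``n_per_class`` for each of the four classes."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    areas: list[SamplingArea] = []
    for label in ClassLabel:
        for _ in range(n_per_class):
            patch = _render_patch(label, patch_px, rng)
            areas.append(SamplingArea(patch=patch, label=label))
    return areas


def generate_failure_suite(
    seed: int = 0, n_each: int = 1
) -> list[tuple[SlideImage, SlideGroundTruth, str]]:
    """Paired clean / bubble / jagged-edge slides on identical geometry.

    Bubbles add spurious high-gradient rims that can masquerade as line
    edges; jagged edges smear the profile peaks.  Each triple shares
    grid geometry, rotation and labels, so detection quality can be
    compared like-for-like.
    """
    out = []
    rng = np.random.default_rng(seed)
    for i in range(n_each):
        base = dict(
            rotation_deg=float(rng.uniform(-15, 15)),
            grid_spacing_px=int(rng.integers(220, 300)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for tag, extra in (
            ("control", {}),
            ("bubbles", {"n_bubbles": 6}),
            ("jagged", {"jag_amplitude_px": 8.0}),
        ):
            img, gt = generate_slide(SlidePhantomSpec(**base, **extra))
            out.append((img, gt, tag))
    return out
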