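"""Grid deskew from a gradient-orientation histogram.

A slide photographed at an angle shows its orthogonal grid rotated by
some unknown theta.  Because the grid dominates the image's strong
gradients, the histogram of gradient directions (folded modulo 90°, the
grid being orthogonal) has a single dominant peak at theta; rotating the
image by the minimum angle that moves that peak to 0° makes the grid
axis-aligned, which is what the downstream projection-profile detector
requires.

Angle convention: positive angles rotate content counter-clockwise in
x-right / y-up coordinates (clockwise as displayed on screen).  With
this convention an image rotated by +theta produces a folded histogram
peak at theta mod 90, and the correction returned by the estimator is
the angle to feed straight back into :func:`rotate_image`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

from .core import SlideImage

log = logging.getLogger(__name__)

#: ITU-R BT.601 luminance weights used to collapse RGB to one channel.
_LUMA = np.array([0.299, 0.587, 0.114])


def luminance(pixels: np.ndarray) -> np.ndarray:
    """RGB (H, W, 3) -> float64 luminance (H, W) in [0, 255]."""
    return np.asarray(pixels, dtype=np.float64) @ _LUMA


@dataclass
class GradientField:
    """Per-pixel Sobel derivatives of the luminance channel."""

    gx: np.ndarray
    gy: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.gx, self.gy)

    @property
    def direction_deg(self) -> np.ndarray:
        """Gradient direction, degrees in (-180, 180]."""
        return np.degrees(np.arctan2(self.gy, self.gx))


@dataclass
class DirectionHistogram:
    """Magnitude-weighted histogram of gradient directions folded mod 90°.

    Bin ``k`` is centered on ``k * bin_width`` degrees (the fold wraps,
    so directions within half a bin of 90° also land in bin 0).
    """

    counts: np.ndarray
    bin_width: float

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width

    @property
    def total_mass(self) -> float:
        return float(self.counts.sum())


@dataclass
class RotationEstimate:
    """Correction angle (degrees, in (-45, 45]) and a peak-sharpness confidence."""

    angle_deg: float
    confidence: float
    reliable: bool = True

    def __post_init__(self) -> None:
        if abs(self.angle_deg) > 45.0 + 1e-9:
            raise ValueError(f"|angle| must be <= 45, got {self.angle_deg}")


def compute_gradients(image: SlideImage | np.ndarray) -> GradientField:
    """3x3 Sobel derivatives of the luminance channel (reflect-padded)."""
    px = image.pixels if isinstance(image, SlideImage) else np.asarray(image)
    lum = luminance(px) if px.ndim == 3 else px.astype(np.float64)
    if lum.shape[0] < 3 or lum.shape[1] < 3:
        raise ValueError(f"image {lum.shape} smaller than the 3x3 Sobel kernel")
    gx = ndimage.sobel(lum, axis=1, mode="reflect")
    gy = ndimage.sobel(lum, axis=0, mode="reflect")
    return GradientField(gx=gx, gy=gy)


def direction_histogram(
    grad: GradientField,
    bin_width_deg: float = 1.0,
    magnitude_floor_quantile: float = 0.75,
) -> DirectionHistogram:
    """Fold gradient directions modulo 90° into a magnitude-weighted histogram.

    Pixels whose gradient magnitude falls below the given quantile of
    the nonzero magnitudes are excluded, so that weak root/background
    texture does not swamp the grid-edge orientations.
    """
    if not np.isclose(90.0 / bin_width_deg, round(90.0 / bin_width_deg)):
        raise ValueError(f"bin width {bin_width_deg} must divide 90 evenly")
    n_bins = int(round(90.0 / bin_width_deg))
    mag = grad.magnitude
    nz = mag[mag > 0]
    if nz.size == 0:
        raise ValueError("all-zero gradient field: rotation cannot be estimated")
    floor = np.quantile(nz, magnitude_floor_quantile) if magnitude_floor_quantile > 0 else 0.0
    mask = mag >= max(floor, np.finfo(float).tiny)
    if not mask.any():
        raise ValueError("no gradient pixels above the magnitude floor")
    folded = np.degrees(np.arctan2(grad.gy[mask], grad.gx[mask])) % 90.0
    # shift by half a bin so bin k is *centered* on k * bin_width
    idx = (np.floor(folded / bin_width_deg + 0.5).astype(int)) % n_bins
    counts = np.bincount(idx, weights=mag[mask], minlength=n_bins)
    return DirectionHistogram(counts=counts, bin_width=bin_width_deg)


def estimate_rotation_angle(hist: DirectionHistogram) -> RotationEstimate:
    """Locate the dominant folded peak and return the minimal correction.

    The peak position theta* in [0, 90) is refined to sub-bin accuracy
    with circular parabolic interpolation over the three bins around the
    maximum.  The correction is -theta* for theta* < 45 and 90 - theta*
    otherwise (at exactly 45° the positive correction is chosen).  A
    histogram with no peak above 2x the uniform level is flagged
    unreliable rather than raising.
    """
    counts = np.asarray(hist.counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty direction histogram")
    n = len(counts)
    k = int(np.argmax(counts))
    y1, y2, y3 = counts[(k - 1) % n], counts[k], counts[(k + 1) % n]
    denom = y1 - 2.0 * y2 + y3
    delta = 0.0 if denom == 0 else float(np.clip(0.5 * (y1 - y3) / denom, -0.5, 0.5))
    theta = ((k + delta) * hist.bin_width) % 90.0
    angle = 90.0 - theta if theta >= 45.0 else -theta
    confidence = float(counts[k] / total)
    reliable = counts[k] > 2.0 * total / n
    if not reliable:
        log.warning(
            "flat direction histogram (peak share %.3f): rotation estimate unreliable",
            confidence,
        )
    return RotationEstimate(angle_deg=float(angle), confidence=confidence, reliable=reliable)


def rotate_image(
    pixels: np.ndarray,
    angle_deg: float,
    expand: bool = False,
    fill: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Rotate an RGB raster about its center (bilinear, constant fill).

    Positive angles follow the package convention (counter-clockwise in
    y-up coordinates).  ``fill`` defaults to the per-channel median of
    the input, a neutral stand-in for the slide background.
    """
    px = np.asarray(pixels)
    if angle_deg == 0.0 and not expand:
        return px.copy()
    if fill is None:
        fill = np.median(px.reshape(-1, px.shape[2]), axis=0)
    out = []
    for c in range(px.shape[2]):
        ch = _sk_rotate(
            px[..., c].astype(np.float64),
            -angle_deg,  # skimage's positive direction is opposite to ours
            resize=expand,
            order=1,
            mode="constant",
            cval=float(fill[c]),
            preserve_range=True,
        )
        out.append(ch)
    return np.clip(np.stack(out, axis=-1), 0, 255).astype(np.uint8)


def rotate_points(points_xy: np.ndarray, angle_deg: float, shape_hw: tuple[int, int]) -> np.ndarray:
    """Map (x, y) points through the same rotation :func:`rotate_image` applies.

    For our angle convention the forward map is the standard rotation
    matrix about the image center: ``dst = R(angle) (src - c) + c``.
    Only the canvas-preserving (non-expanding) rotation is supported.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    h, w = shape_hw
    center = np.array([w, h], dtype=float) / 2.0 - 0.5
    t = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return (pts - center) @ rot.T + center


def normalize_rotation(image: SlideImage, est: RotationEstimate, expand: bool = False) -> SlideImage:
    """Rotate *image* by the estimated correction so the grid is axis-aligned."""
    px = rotate_image(image.pixels, est.angle_deg, expand=expand)
    log.info("deskewed %s by %+.2f deg (confidence %.3f)", image.source_id, est.angle_deg, est.confidence)
    return SlideImage(pixels=px, source_id=image.source_id)


def _fold_correction(angle: float) -> float:
    """Map an accumulated correction into the canonical (-45, 45] range."""
    a = (angle + 45.0) % 90.0 - 45.0
    return 45.0 if a == -45.0 else a


def _estimate_once(
    pixels: np.ndarray,
    bin_width_deg: float,
    magnitude_floor_quantile: float,
    presmooth_sigma: float,
) -> RotationEstimate:
    lum = luminance(pixels)
    if presmooth_sigma > 0:
        lum = ndimage.gaussian_filter(lum, presmooth_sigma)
    grad = compute_gradients(lum)
    hist = direction_histogram(grad, bin_width_deg, magnitude_floor_quantile)
    return estimate_rotation_angle(hist)


def estimate_rotation(
    image: SlideImage,
    bin_width_deg: float = 1.0,
    magnitude_floor_quantile: float = 0.75,
    presmooth_sigma: float = 1.5,
    refine_passes: int = 2,
) -> RotationEstimate:
    """Estimate the deskew correction for a slide, with refinement.

    A light Gaussian pre-smoothing suppresses the resampling staircase
    of tilted edges, whose axis-aligned runs otherwise bias the
    direction histogram toward 0/90° at intermediate angles.  Because
    the estimator is most accurate near zero, up to ``refine_passes``
    residual estimates on the provisionally deskewed image are folded
    into the returned correction.
    """
    est = _estimate_once(image.pixels, bin_width_deg, magnitude_floor_quantile, presmooth_sigma)
    total = est.angle_deg
    confidence = est.confidence
    residual = est.angle_deg
    if est.reliable:
        for _ in range(refine_passes):
            if abs(residual) < 0.05:
                break
            deskewed = rotate_image(image.pixels, total)
            est_r = _estimate_once(deskewed, bin_width_deg, magnitude_floor_quantile, presmooth_sigma)
            if not est_r.reliable:
                break
            residual = est_r.angle_deg
            total = _fold_correction(total + residual)
            confidence = est_r.confidence
    return RotationEstimate(angle_deg=_fold_correction(total), confidence=confidence, reliable=est.reliable)
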