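"""Shared domain types and run configuration.

Coordinate convention, used everywhere in the package: pixel coordinates
are 0-based with ``x`` = column and ``y`` = row, origin at the top-left
corner; boxes are half-open rectangles ``[x0, x1) x [y0, y1)``.  Angles
are degrees, positive in the x-right / y-up mathematical sense (which is
clockwise on screen, where y points down).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml


class ClassLabel(enum.IntEnum):
    """Colonization class of one sampling area.

    ``VESICLES`` and ``ARBUSCULES`` mark fungal structures in the root;
    ``NEGATIVE`` is root tissue with no visible colonization; ``NO_ROOT``
    is a grid crossing with no root under it.  Crossings showing hyphae
    only are counted with arbuscules (single merged class).
    """

    VESICLES = 0
    ARBUSCULES = 1
    NEGATIVE = 2
    NO_ROOT = 3


LABEL_NAMES = {
    ClassLabel.VESICLES: "vesicles",
    ClassLabel.ARBUSCULES: "arbuscules",
    ClassLabel.NEGATIVE: "negative",
    ClassLabel.NO_ROOT: "no_root",
}


def validate_label(value: int) -> ClassLabel:
    """Coerce *value* to a :class:`ClassLabel`, raising ``ValueError`` otherwise."""
    try:
        return ClassLabel(int(value))
    except ValueError:
        raise ValueError(
            f"invalid class label {value!r}: must be one of "
            "{0 (vesicles), 1 (arbuscules), 2 (negative), 3 (no_root)}"
        ) from None


@dataclass
class SlideImage:
    """An RGB slide photograph: the unit of intersection detection.

    ``pixels`` is a ``(height, width, 3)`` uint8 array.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got shape {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(f"image too small: {px.shape[1]}x{px.shape[0]}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class IntersectionBox:
    """Axis-aligned half-open rectangle marking one sampling area."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate box {self.as_tuple()}: x1 > x0 and y1 > y0 required")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        # center of the covered pixel lattice, hence the -1 (half-open bound)
        return ((self.x0 + self.x1 - 1) / 2.0, (self.y0 + self.y1 - 1) / 2.0)

    def clipped(self, width_px: int, height_px: int) -> Optional["IntersectionBox"]:
        """Clip to image bounds; ``None`` when nothing remains."""
        x0, y0 = max(self.x0, 0), max(self.y0, 0)
        x1, y1 = min(self.x1, width_px), min(self.y1, height_px)
        if x1 <= x0 or y1 <= y0:
            return None
        return IntersectionBox(x0, y0, x1, y1)

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.y0 : self.y1, self.x0 : self.x1]


def box_around(cx: float, cy: float, half_extent: int) -> IntersectionBox:
    """Square box of side ``2 * half_extent`` centered at ``(cx, cy)``."""
    x0 = int(round(cx)) - half_extent
    y0 = int(round(cy)) - half_extent
    return IntersectionBox(x0, y0, x0 + 2 * half_extent, y0 + 2 * half_extent)


@dataclass
class SamplingArea:
    """The image patch at one grid crossing, the unit that gets classified."""

    patch: np.ndarray
    source_box: Optional[IntersectionBox] = None
    label: Optional[ClassLabel] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.patch)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"patch must be (H, W, 3), got {p.shape}")
        if p.shape[0] != p.shape[1]:
            raise ValueError(f"patch must be square, got {p.shape[1]}x{p.shape[0]}")
        self.patch = p.astype(np.uint8, copy=False)
        if self.label is not None:
            self.label = validate_label(self.label)

    def resized(self, size: int) -> np.ndarray:
        """Patch resampled to ``size x size`` with bilinear interpolation."""
        from PIL import Image

        if self.patch.shape[0] == size:
            return self.patch
        im = Image.fromarray(self.patch).resize((size, size), Image.BILINEAR)
        return np.asarray(im)


@dataclass
class RunConfig:
    """Tunable pipeline parameters.

    peak_distance
        Minimum separation (px) between projection-profile peaks; the
        highest peak wins inside this radius.
    smoothing_sigma
        Gaussian sigma (px) applied to profiles before peak detection.
    max_line_width_px
        Maximum edge-to-edge gap treated as one grid line.  ``None``
        (default) picks the split between the "line width" and "line
        spacing" gap clusters adaptively from the detected peaks.
    line_spacing_ratio
        Physical line-width / line-spacing ratio of the slide grid
        (0.25 mm lines on a 1.00 mm pitch -> 0.25); used to size lines
        recovered from a single edge.
    box_half_extent
        Half side (px) of the sampling-area box (75 -> 150 px boxes at
        the nominal 1008 x 756 input scale).
    min_clipped_area_frac
        Boxes at the image border keeping less than this fraction of
        their nominal area are dropped.
    min_peak_rel_height
        Profile peaks below this fraction of the tallest peak are
        ignored when building lines: a genuine grid-line edge projects
        over the full image extent, so its peak dwarfs root-texture
        and noise bumps.
    bin_width_deg, magnitude_floor_quantile, rotation_presmooth_sigma
        Direction-histogram bin width, the gradient-magnitude quantile
        below which pixels are ignored, and the Gaussian blur applied
        before the deskew gradients (suppresses resampling staircase
        bias).
    """

    peak_distance: int = 50
    smoothing_sigma: float = 3.0
    min_peak_rel_height: float = 0.25
    max_line_width_px: Optional[int] = None
    line_spacing_ratio: float = 0.25
    box_half_extent: int = 75
    min_clipped_area_frac: float = 0.5
    bin_width_deg: float = 1.0
    magnitude_floor_quantile: float = 0.75
    rotation_presmooth_sigma: float = 1.5
    keep_single_edges: bool = True
    expand_canvas: bool = False
    classifier_kind: str = "svm"
    extractor: str = "handcrafted"
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.peak_distance <= 0:
            raise ValueError("peak_distance must be > 0")
        if not (0.0 < self.line_spacing_ratio < 1.0):
            raise ValueError("line_spacing_ratio must lie in (0, 1)")
        if self.box_half_extent <= 0:
            raise ValueError("box_half_extent must be > 0")
        if not (0.0 <= self.min_clipped_area_frac <= 1.0):
            raise ValueError("min_clipped_area_frac must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
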