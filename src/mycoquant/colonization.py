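"""Colonization proportions from per-intersection class tallies.

With N_s sampling areas of which N_nr fall on no root, N_a show
arbuscules and N_v show vesicles, the arbuscular and vesicular
colonization proportions are

    AC = N_a / (N_s - N_nr),    VC = N_v / (N_s - N_nr).

The negative count appears in no formula; it is kept for reporting.
When every sampling area is rootless (N_s = N_nr) both proportions are
undefined and reported as such, never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import ClassLabel, validate_label

log = logging.getLogger(__name__)

#: below this many sampling areas the manual protocol is considered
#: under-sampled; we warn rather than refuse.
MIN_SAMPLING_AREAS = 200


@dataclass(frozen=True)
class ClassCounts:
    """Per-class tallies of sampling areas."""

    n_vesicles: int = 0
    n_arbuscules: int = 0
    n_negative: int = 0
    n_no_root: int = 0

    def __post_init__(self) -> None:
        for name in ("n_vesicles", "n_arbuscules", "n_negative", "n_no_root"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_vesicles + self.n_arbuscules + self.n_negative + self.n_no_root

    def __add__(self, other: "ClassCounts") -> "ClassCounts":
        return ClassCounts(
            self.n_vesicles + other.n_vesicles,
            self.n_arbuscules + other.n_arbuscules,
            self.n_negative + other.n_negative,
            self.n_no_root + other.n_no_root,
        )


@dataclass
class ColonizationResult:
    """Class counts plus the AC / VC proportions (``None`` when undefined)."""

    counts: ClassCounts
    ac: Optional[float]
    vc: Optional[float]
    low_sample_warning: bool = False

    @property
    def defined(self) -> bool:
        return self.ac is not None


def count_classes(labels: Iterable[int]) -> ClassCounts:
    """Tally a label sequence into :class:`ClassCounts`."""
    tally = {c: 0 for c in ClassLabel}
    n = 0
    for raw in labels:
        tally[validate_label(raw)] += 1
        n += 1
    counts = ClassCounts(
        n_vesicles=tally[ClassLabel.VESICLES],
        n_arbuscules=tally[ClassLabel.ARBUSCULES],
        n_negative=tally[ClassLabel.NEGATIVE],
        n_no_root=tally[ClassLabel.NO_ROOT],
    )
    assert counts.n_total == n
    return counts


def colonization_degrees(counts: ClassCounts) -> ColonizationResult:
    """Apply the AC / VC formulas to a tally.

    The denominator is the number of sampling areas that actually
    contain root (N_s - N_nr); a tally with no rooted areas yields an
    undefined (flagged) result.
    """
    denom = counts.n_total - counts.n_no_root
    low = counts.n_total < MIN_SAMPLING_AREAS
    if low:
        log.warning(
            "only %d sampling areas (< %d): proportions may be unstable",
            counts.n_total,
            MIN_SAMPLING_AREAS,
        )
    if denom == 0:
        log.warning("no rooted sampling areas: AC/VC undefined")
        return ColonizationResult(counts=counts, ac=None, vc=None, low_sample_warning=low)
    ac = counts.n_arbuscules / denom
    vc = counts.n_vesicles / denom
    assert 0.0 <= ac <= 1.0 and 0.0 <= vc <= 1.0 and ac + vc <= 1.0 + 1e-12
    return ColonizationResult(counts=counts, ac=ac, vc=vc, low_sample_warning=low)


def quantify_labels(labels: Iterable[int]) -> ColonizationResult:
    """Convenience: tally labels and compute proportions in one step."""
    return colonization_degrees(count_classes(labels))
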