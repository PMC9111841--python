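"""Raster and result input/output.

Readers accept PNG, JPEG and TIFF and always hand back RGB rasters;
results go out as JSON (nested, lossless round-trip) plus a flat CSV
with one row per sampling area.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from .core import ClassLabel, IntersectionBox, LABEL_NAMES, SlideImage, validate_label
from .colonization import ClassCounts, ColonizationResult

log = logging.getLogger(__name__)

_SUPPORTED = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def read_image(path: str | Path) -> SlideImage:
    """Read a PNG/JPEG/TIFF file as an RGB :class:`SlideImage`.

    Grayscale inputs are replicated across the three channels; alpha is
    dropped.  JPEG pixels are used exactly as decoded.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if path.suffix.lower() not in _SUPPORTED:
        raise ValueError(f"unsupported image format {path.suffix!r} for {path}")
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("I", "I;16", "F"):
                arr = np.asarray(im, dtype=np.float64)
                scale = 257.0 if arr.max() > 255 else 1.0
                arr = np.clip(arr / scale, 0, 255).astype(np.uint8)
                px = np.stack([arr] * 3, axis=-1)
            else:
                if im.mode != "RGB":
                    im = im.convert("RGB")
                px = np.asarray(im)
    except UnidentifiedImageError:
        raise ValueError(f"not a decodable image file: {path}") from None
    except OSError as exc:
        raise IOError(f"failed to read image {path}: {exc}") from exc
    return SlideImage(pixels=px, source_id=path.name)


def write_image(image: SlideImage | np.ndarray, path: str | Path) -> None:
    """Write an RGB raster to *path* (format chosen by extension)."""
    px = image.pixels if isinstance(image, SlideImage) else np.asarray(image, dtype=np.uint8)
    try:
        Image.fromarray(px).save(Path(path))
    except OSError as exc:
        raise IOError(f"failed to write image {path}: {exc}") from exc


def _box_record(box: IntersectionBox, label: Optional[ClassLabel]) -> dict:
    rec = {"x0": box.x0, "y0": box.y0, "x1": box.x1, "y1": box.y1}
    rec["label"] = int(label) if label is not None else None
    rec["label_name"] = LABEL_NAMES[label] if label is not None else None
    return rec


def write_results(
    result: ColonizationResult,
    boxes: Sequence[IntersectionBox],
    labels: Sequence[Optional[ClassLabel]],
    json_path: str | Path,
    csv_path: Optional[str | Path] = None,
    image_id: str = "",
    image_size: Optional[tuple[int, int]] = None,
) -> None:
    """Serialize a colonization result with its per-box labels.

    JSON carries the full nested result; the optional CSV is one row per
    sampling area.  Undefined AC/VC (no root anywhere) serialize as
    ``null``, never as 0.
    """
    if len(boxes) != len(labels):
        raise ValueError(f"{len(boxes)} boxes but {len(labels)} labels")
    if image_size is not None:
        w, h = image_size
        for b in boxes:
            if b.x0 < 0 or b.y0 < 0 or b.x1 > w or b.y1 > h:
                raise ValueError(f"box {b.as_tuple()} outside image bounds {w}x{h}")
    c = result.counts
    payload = {
        "image": image_id,
        "n_intersections": c.n_total,
        "counts": {
            "vesicles": c.n_vesicles,
            "arbuscules": c.n_arbuscules,
            "negative": c.n_negative,
            "no_root": c.n_no_root,
        },
        "AC": result.ac,
        "VC": result.vc,
        "low_sample_warning": result.low_sample_warning,
        "boxes": [_box_record(b, l) for b, l in zip(boxes, labels)],
    }
    json_path = Path(json_path)
    try:
        json_path.parent.mkdir(parents=True, exist_ok=True)
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise IOError(f"failed to write results to {json_path}: {exc}") from exc
    if csv_path is not None:
        with open(Path(csv_path), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", "x0", "y0", "x1", "y1", "label", "label_name"])
            for b, l in zip(boxes, labels):
                writer.writerow(
                    [
                        image_id,
                        b.x0,
                        b.y0,
                        b.x1,
                        b.y1,
                        int(l) if l is not None else "",
                        LABEL_NAMES[l] if l is not None else "",
                    ]
                )
    log.info("wrote results for %s: %d sampling areas", image_id or "<image>", c.n_total)


def read_results(json_path: str | Path) -> tuple[ColonizationResult, list[IntersectionBox], list[Optional[ClassLabel]]]:
    """Inverse of :func:`write_results` for the JSON artifact."""
    with open(json_path) as fh:
        data = json.load(fh)
    cts = data["counts"]
    counts = ClassCounts(
        n_vesicles=cts["vesicles"],
        n_arbuscules=cts["arbuscules"],
        n_negative=cts["negative"],
        n_no_root=cts["no_root"],
    )
    result = ColonizationResult(
        counts=counts,
        ac=data["AC"],
        vc=data["VC"],
        low_sample_warning=data["low_sample_warning"],
    )
    boxes, labels = [], []
    for rec in data["boxes"]:
        boxes.append(IntersectionBox(rec["x0"], rec["y0"], rec["x1"], rec["y1"]))
        labels.append(validate_label(rec["label"]) if rec["label"] is not None else None)
    return result, boxes, labels
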