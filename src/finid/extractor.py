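"""Square identification-chip extraction.

Turns a detected bounding box on the original photograph into a square
chip for classification, without ever padding: the box is squarified on
its larger side, shifted minimally to stay inside the image (clamping
the side to the smaller image dimension when necessary), cropped, and
resampled to the chip size — bilinear when up-sampling, area-averaging
when down-sampling. Every chip pixel therefore originates from the
source photograph.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["Chip", "squarify_box", "extract_chip", "write_chips"]

CHIP_SIZE = 512


@dataclass
class Chip:
    """A square RGB chip plus provenance back to its source detection."""
    pixels: np.ndarray                # (size, size, 3) uint8
    source_image: Path | None
    source_box: tuple                 # normalized (cx, cy, w, h)
    effective_crop: tuple             # pixel rect (x0, y0, x1, y1), half-open
    resize_factor: float              # chip_size / crop side


def squarify_box(box, image_size):
    """Make a pixel rectangle square and keep it inside the image.

    ``box`` is (x0, y0, x1, y1) half-open pixel coordinates; ``image_size``
    is (height, width). The square side is the larger box dimension,
    clamped to the smaller image dimension; the square is centered on the
    box center, then translated the minimal distance needed to lie fully
    inside the image.
    """
    h, w = image_size
    x0, y0, x1, y1 = box
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"degenerate box {box}")
    if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
        raise ValueError(f"box {box} lies outside the image")
    side = int(round(max(x1 - x0, y1 - y0)))
    side = min(side, h, w)
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    nx0 = int(round(cx - side / 2.0))
    ny0 = int(round(cy - side / 2.0))
    nx0 = min(max(nx0, 0), w - side)
    ny0 = min(max(ny0, 0), h - side)
    return (nx0, ny0, nx0 + side, ny0 + side)


def extract_chip(image: np.ndarray, box, chip_size: int = CHIP_SIZE,
                 source_image=None) -> Chip:
    """Extract a square chip around a normalized (cx, cy, w, h) box.

    The box is denormalized by the image shape, squarified, cropped and
    resampled to ``chip_size``; no padding is ever introduced.
    """
    h, w = image.shape[:2]
    cx, cy, bw, bh = box[:4]
    px = (cx * w - bw * w / 2.0, cy * h - bh * h / 2.0,
          cx * w + bw * w / 2.0, cy * h + bh * h / 2.0)
    rect = squarify_box(px, (h, w))
    x0, y0, x1, y1 = rect
    crop = image[y0:y1, x0:x1]
    side = x1 - x0
    if side == chip_size:
        pixels = crop.copy()
    else:
        im = Image.fromarray(crop)
        resample = Image.BILINEAR if side < chip_size else Image.BOX
        pixels = np.asarray(im.resize((chip_size, chip_size), resample))
    return Chip(pixels=pixels, source_image=source_image,
                source_box=tuple(float(v) for v in box[:4]),
                effective_crop=rect, resize_factor=chip_size / side)


def write_chips(chips, out_dir, prefix: str = "chip"):
    """Write chips as PNG plus a provenance CSV; returns the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "chips.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chip_path", "source_image", "cx", "cy", "w", "h",
                         "resize_factor"])
        for i, chip in enumerate(chips):
            name = f"{prefix}_{i:06d}.png"
            Image.fromarray(chip.pixels).save(out / name)
            writer.writerow([name, chip.source_image, *chip.source_box,
                             f"{chip.resize_factor:.6f}"])
    return csv_path
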