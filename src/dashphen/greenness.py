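"""Per-frame canopy greenness: cropping, HSV conversion, ROI masking, GCC.

The Green Chromatic Coordinate, GCC = G / (R + G + B), is the standard
phenocam greenness index: a chromatic ratio that is invariant to a global
multiplicative change in scene brightness, which makes it suitable for
imagery collected under day-to-day illumination drift.

Two computation modes are provided. ``"rgb"`` applies the GCC ratio to the
native R, G, B channels (the standard index, recommended for new analyses).
``"hsv"`` first converts the crop to Hue-Saturation-Value and substitutes
the three HSV channels positionally into the same ratio, i.e.
S / (H + S + V); this variant decouples chromatic content from value but
stretches the resulting index non-linearly, and exists to reproduce
workflows that computed the ratio on HSV-converted crops.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import rgb2hsv

from .detections import BoundingBox

__all__ = [
    "ROI",
    "FrameGreenness",
    "crop",
    "to_hsv",
    "apply_roi",
    "gcc",
    "frame_greenness",
    "save_roi",
    "load_roi",
]


class CoordinateError(ValueError):
    """A box or ROI does not fit inside the image it refers to."""


@dataclass
class ROI:
    """Region of interest inside a cropped tree image.

    Either a rectangle ``(x_min, y_min, x_max, y_max)`` in cropped-image
    pixel coordinates (half-open), or a boolean mask of the cropped image's
    height x width. ROIs are defined relative to the crop so that the same
    canopy portion is sampled on every frame of the season.
    """

    rect: tuple[int, int, int, int] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.mask is None):
            raise ValueError("ROI requires exactly one of rect or mask")
        if self.rect is not None:
            x0, y0, x1, y1 = self.rect
            if not (x0 < x1 and y0 < y1):
                raise ValueError(f"empty ROI rectangle {self.rect}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.ndim != 2:
                raise ValueError("ROI mask must be 2-D")
            if not self.mask.any():
                raise ValueError("ROI mask selects no pixels")


@dataclass(frozen=True)
class FrameGreenness:
    """GCC of one tree on one date, with the pixel count it was computed from."""

    date: dt.date
    tree_id: str
    gcc: float
    n_pixels: int
    mode: str


def crop(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Crop an image to a bounding box; pixel values are unchanged."""
    h, w = image.shape[:2]
    if box.x_min < 0 or box.y_min < 0 or box.x_max > w or box.y_max > h:
        raise CoordinateError(
            f"box ({box.x_min},{box.y_min},{box.x_max},{box.y_max}) outside image {w}x{h}"
        )
    return image[box.y_min : box.y_max, box.x_min : box.x_max]


def to_hsv(image: np.ndarray) -> np.ndarray:
    """Standard hexcone RGB -> HSV transform; all channels scaled to [0, 1]."""
    arr = np.asarray(image)
    if arr.ndim < 2 or arr.shape[-1] != 3:
        raise ValueError("expected a 3-channel RGB array")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    return rgb2hsv(arr)


def apply_roi(image: np.ndarray, roi: ROI | None) -> np.ndarray:
    """Return the pixels inside the ROI as an (n, channels) array.

    With ``roi=None`` all pixels are returned.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    if roi is None:
        return arr.reshape(-1, arr.shape[-1]) if arr.ndim == 3 else arr.reshape(-1, 1)
    if roi.rect is not None:
        x0, y0, x1, y1 = roi.rect
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            raise CoordinateError(f"ROI rectangle {roi.rect} outside image {w}x{h}")
        sub = arr[y0:y1, x0:x1]
        return sub.reshape(-1, arr.shape[-1])
    if roi.mask.shape != (h, w):
        raise CoordinateError(
            f"ROI mask shape {roi.mask.shape} does not match image {h}x{w}"
        )
    return arr[roi.mask]


def gcc(pixels: np.ndarray, mode: str = "hsv", per_pixel: bool = True) -> float:
    """Green Chromatic Coordinate of a pixel collection.

    Parameters
    ----------
    pixels : (n, 3) array
        In ``"rgb"`` mode the columns are R, G, B (uint8 or float); in
        ``"hsv"`` mode the pixels are RGB and are converted, and the H, S, V
        channels are substituted positionally into the same ratio,
        channel2 / (channel1 + channel2 + channel3).
    per_pixel : bool
        If True (default, the phenocam convention) the ratio is computed per
        pixel and averaged; if False the ratio of the channel means is
        returned.

    Pixels whose channel sum is zero (pure black) carry no chromatic
    information and are excluded; if every pixel is excluded, ``nan`` is
    returned as an explicit missing value.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.reshape(-1, arr.shape[-1])
    if arr.ndim != 2 or arr.shape[-1] != 3:
        raise ValueError("expected an (n, 3) pixel array")
    if arr.shape[0] == 0:
        raise ValueError("empty pixel set")
    if mode == "hsv":
        src = np.asarray(pixels)
        scale = 255.0 if src.dtype == np.uint8 or arr.max() > 1.0 else 1.0
        arr = rgb2hsv((arr / scale).reshape(1, -1, 3)).reshape(-1, 3)
    elif mode != "rgb":
        raise ValueError(f"mode must be 'rgb' or 'hsv', got {mode!r}")
    sums = arr.sum(axis=1)
    valid = sums > 0
    if not valid.any():
        return float("nan")
    if per_pixel:
        return float(np.mean(arr[valid, 1] / sums[valid]))
    means = arr[valid].mean(axis=0)
    return float(means[1] / means.sum())


def frame_greenness(
    image: np.ndarray,
    box: BoundingBox,
    roi: ROI | None = None,
    mode: str = "hsv",
    tree_id: str | None = None,
    date: dt.date | None = None,
    per_pixel: bool = True,
) -> FrameGreenness:
    """Convenience: crop to the box, mask with the ROI, and compute GCC."""
    pixels = apply_roi(crop(image, box), roi)
    value = gcc(pixels, mode=mode, per_pixel=per_pixel)
    frame_date = date or box.date
    if frame_date is None:
        raise ValueError("no date available: pass date= or use a dated box")
    return FrameGreenness(
        date=frame_date,
        tree_id=tree_id or box.tree_id or "tree",
        gcc=value,
        n_pixels=int(pixels.shape[0]),
        mode=mode,
    )


def save_roi(rois: dict[str, ROI], path: str | Path) -> None:
    """Persist per-tree rectangular ROIs as JSON (mask ROIs are not serialised)."""
    doc = {}
    for tree_id, roi in rois.items():
        if roi.rect is None:
            raise ValueError(f"ROI for {tree_id!r} is a mask; only rectangles persist to JSON")
        doc[tree_id] = list(roi.rect)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_roi(path: str | Path) -> dict[str, ROI]:
    with open(path) as fh:
        doc = json.load(fh)
    return {tree_id: ROI(rect=tuple(rect)) for tree_id, rect in doc.items()}
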