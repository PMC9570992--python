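"""Bounding-box data model, detection filtering, and precision--recall evaluation.

Detector output arrives as axis-aligned boxes in pixel coordinates with a
confidence score and class label. This module provides the post-processing
cascade applied before any greenness analysis -- removal of boxes that hit
the top edge of the frame, removal of low-confidence boxes, and suppression
of duplicate boxes for the same tree -- plus IoU and mean-average-precision
evaluation against ground truth.

Coordinate convention: pixels are 0-based with the origin at the top-left,
and boxes are half-open ``[min, max)`` so a box's area is
``(x_max - x_min) * (y_max - y_min)`` and ``y_min == 0`` means the box
touches the top edge of the image.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BoundingBox",
    "DetectionSet",
    "EmptyTruthError",
    "iou",
    "filter_edge_boxes",
    "filter_low_confidence",
    "deduplicate",
    "mean_average_precision",
    "read_detections_csv",
    "write_detections_csv",
    "read_coco_json",
    "write_coco_json",
]

CSV_COLUMNS = ["date", "tree_id", "x_min", "y_min", "x_max", "y_max", "confidence", "class"]


class EmptyTruthError(ValueError):
    """Raised when evaluation is requested against an empty ground-truth set."""


@dataclass(frozen=True)
class BoundingBox:
    """A single detection or ground-truth box.

    ``confidence`` is ``None`` for ground-truth annotations, which carry no
    detector score.
    """

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    confidence: float | None = None
    class_label: str = "Tree"
    date: dt.date | None = None
    tree_id: str | None = None

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError(f"x_min must be < x_max, got [{self.x_min}, {self.x_max})")
        if not self.y_min < self.y_max:
            raise ValueError(f"y_min must be < y_max, got [{self.y_min}, {self.y_max})")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def shifted(self, dx: int, dy: int) -> "BoundingBox":
        return replace(
            self,
            x_min=self.x_min + dx,
            x_max=self.x_max + dx,
            y_min=self.y_min + dy,
            y_max=self.y_max + dy,
        )


@dataclass
class DetectionSet:
    """A collection of boxes sharing one image coordinate frame."""

    records: list[BoundingBox] = field(default_factory=list)
    image_size: tuple[int, int] | None = None  # (width, height)

    def __post_init__(self) -> None:
        if self.image_size is not None:
            w, h = self.image_size
            for b in self.records:
                if b.x_min < 0 or b.y_min < 0 or b.x_max > w or b.y_max > h:
                    raise ValueError(
                        f"box ({b.x_min},{b.y_min},{b.x_max},{b.y_max}) outside "
                        f"image bounds {w}x{h}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes under the half-open convention.

    Symmetric, 1.0 for identical boxes, 0.0 for disjoint boxes.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def filter_edge_boxes(
    dets: DetectionSet, *, include_x_edges: bool = False
) -> tuple[DetectionSet, int]:
    """Remove boxes whose top edge touches the top of the image (``y_min == 0``).

    A detection that has grown to the image border has typically failed to
    enclose the tree. With ``include_x_edges=True`` boxes touching the left
    edge (``x_min == 0``) are removed as well; the default matches the
    y-only rule. Survivor order is preserved.
    """
    kept = []
    for b in dets.records:
        hit = b.y_min == 0 or (include_x_edges and b.x_min == 0)
        if not hit:
            kept.append(b)
    return DetectionSet(kept, dets.image_size), len(dets.records) - len(kept)


def filter_low_confidence(
    dets: DetectionSet, threshold: float = 0.30
) -> tuple[DetectionSet, int]:
    """Remove boxes with confidence strictly below ``threshold``.

    A box at exactly the threshold is kept. Boxes without a confidence
    (ground truth) are kept unconditionally.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    kept = [b for b in dets.records if b.confidence is None or b.confidence >= threshold]
    return DetectionSet(kept, dets.image_size), len(dets.records) - len(kept)


def deduplicate(dets: DetectionSet, iou_merge_threshold: float = 0.5) -> DetectionSet:
    """Suppress duplicate boxes for the same tree on the same date.

    Within each (date, class) group, boxes are visited in descending
    confidence (ties broken by input order); a box overlapping an
    already-kept box with IoU strictly greater than ``iou_merge_threshold``
    is dropped, so exactly the highest-confidence box of each overlap group
    survives. Output preserves the original input order of survivors.
    """
    groups: dict[tuple, list[tuple[int, BoundingBox]]] = {}
    for idx, b in enumerate(dets.records):
        groups.setdefault((b.date, b.class_label), []).append((idx, b))

    kept_idx: set[int] = set()
    for members in groups.values():
        ordered = sorted(
            members, key=lambda ib: (-(ib[1].confidence if ib[1].confidence is not None else 1.0), ib[0])
        )
        kept_boxes: list[BoundingBox] = []
        for idx, b in ordered:
            if any(iou(b, k) > iou_merge_threshold for k in kept_boxes):
                continue
            kept_boxes.append(b)
            kept_idx.add(idx)

    kept = [b for i, b in enumerate(dets.records) if i in kept_idx]
    return DetectionSet(kept, dets.image_size)


def _average_precision(
    dets: Sequence[BoundingBox], truth: Sequence[BoundingBox], iou_threshold: float
) -> float:
    """AP for one class: greedy confidence-ordered matching, all-point interpolation."""
    n_truth = len(truth)
    order = sorted(
        range(len(dets)),
        key=lambda i: (-(dets[i].confidence if dets[i].confidence is not None else 1.0), i),
    )
    matched = [False] * n_truth
    tp = np.zeros(len(dets))
    for rank, i in enumerate(order):
        d = dets[i]
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truth):
            if matched[j] or t.date != d.date:
                continue
            v = iou(d, t)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            tp[rank] = 1.0
    if len(dets) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_truth
    precision = cum_tp / np.arange(1, len(dets) + 1)
    # all-point interpolation: running max of precision from the right,
    # integrated over recall increments
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * prec_env))


def mean_average_precision(
    dets: DetectionSet, truth: DetectionSet, iou_threshold: float = 0.5
) -> float:
    """Mean average precision of detections against ground truth.

    Detections are sorted by descending confidence and matched greedily,
    one-to-one, to unmatched truth boxes of the same date at
    ``IoU >= iou_threshold``. AP is the area under the resulting
    precision--recall curve with all-point interpolation; the mean is taken
    over the classes present in the truth set (with a single class,
    mAP = AP).
    """
    if len(truth) == 0:
        raise EmptyTruthError("ground-truth set is empty: recall is undefined")
    classes = sorted({t.class_label for t in truth.records})
    aps = []
    for cls in classes:
        d_cls = [b for b in dets.records if b.class_label == cls]
        t_cls = [b for b in truth.records if b.class_label == cls]
        aps.append(_average_precision(d_cls, t_cls, iou_threshold))
    return float(np.mean(aps))


# ---------------------------------------------------------------------------
# I/O: tidy CSV and COCO-style JSON


def write_detections_csv(dets: DetectionSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for b in dets.records:
            writer.writerow(
                [
                    b.date.isoformat() if b.date else "",
                    b.tree_id or "",
                    b.x_min,
                    b.y_min,
                    b.x_max,
                    b.y_max,
                    "" if b.confidence is None else f"{b.confidence:.6g}",
                    b.class_label,
                ]
            )


def read_detections_csv(
    path: str | Path, image_size: tuple[int, int] | None = None
) -> DetectionSet:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                BoundingBox(
                    x_min=int(row["x_min"]),
                    y_min=int(row["y_min"]),
                    x_max=int(row["x_max"]),
                    y_max=int(row["y_max"]),
                    confidence=float(row["confidence"]) if row.get("confidence") else None,
                    class_label=row.get("class") or "Tree",
                    date=dt.date.fromisoformat(row["date"]) if row.get("date") else None,
                    tree_id=row.get("tree_id") or None,
                )
            )
    return DetectionSet(records, image_size)


def write_coco_json(dets: DetectionSet, path: str | Path) -> None:
    """Write a COCO-style annotation file (bbox as [x, y, width, height])."""
    dates = sorted({b.date for b in dets.records if b.date is not None})
    img_ids = {d: i + 1 for i, d in enumerate(dates)}
    classes = sorted({b.class_label for b in dets.records})
    cat_ids = {c: i + 1 for i, c in enumerate(classes)}
    w, h = dets.image_size if dets.image_size else (None, None)
    doc = {
        "images": [
            {"id": img_ids[d], "file_name": f"{d.isoformat()}.png", "width": w, "height": h}
            for d in dates
        ],
        "categories": [{"id": cat_ids[c], "name": c} for c in classes],
        "annotations": [],
    }
    for i, b in enumerate(dets.records):
        ann = {
            "id": i + 1,
            "image_id": img_ids[b.date] if b.date else 0,
            "category_id": cat_ids[b.class_label],
            "bbox": [b.x_min, b.y_min, b.width, b.height],
            "area": b.area,
            "iscrowd": 0,
        }
        if b.confidence is not None:
            ann["score"] = b.confidence
        if b.tree_id:
            ann["tree_id"] = b.tree_id
        doc["annotations"].append(ann)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_coco_json(path: str | Path) -> DetectionSet:
    with open(path) as fh:
        doc = json.load(fh)
    img_by_id = {im["id"]: im for im in doc.get("images", [])}
    cat_by_id = {c["id"]: c["name"] for c in doc.get("categories", [])}
    size = None
    for im in img_by_id.values():
        if im.get("width") and im.get("height"):
            size = (im["width"], im["height"])
            break
    records = []
    for ann in doc.get("annotations", []):
        x, y, w, h = ann["bbox"]
        im = img_by_id.get(ann.get("image_id"))
        date = None
        if im and im.get("file_name"):
            stem = Path(im["file_name"]).stem
            try:
                date = dt.date.fromisoformat(stem)
            except ValueError:
                date = None
        records.append(
            BoundingBox(
                x_min=int(x),
                y_min=int(y),
                x_max=int(x + w),
                y_max=int(y + h),
                confidence=ann.get("score"),
                class_label=cat_by_id.get(ann.get("category_id"), "Tree"),
                date=date,
                tree_id=ann.get("tree_id"),
            )
        )
    return DetectionSet(records, size)
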