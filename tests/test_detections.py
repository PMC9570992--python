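"""Bounding-box filters, IoU, and mean-average-precision evaluation."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dashphen.detections import (
    BoundingBox,
    DetectionSet,
    EmptyTruthError,
    deduplicate,
    filter_edge_boxes,
    filter_low_confidence,
    iou,
    mean_average_precision,
    read_coco_json,
    read_detections_csv,
    write_coco_json,
    write_detections_csv,
)

from conftest import A_DATE, boxes


def box(x0, y0, x1, y1, conf=None, date=A_DATE, **kw):
    return BoundingBox(x_min=x0, y_min=y0, x_max=x1, y_max=y1, confidence=conf, date=date, **kw)


def iou_rasterized(a, b):
    """Independent IoU oracle: paint both boxes on a pixel grid and count."""
    w = max(a.x_max, b.x_max) + 1
    h = max(a.y_max, b.y_max) + 1
    ga = np.zeros((h, w), bool)
    gb = np.zeros((h, w), bool)
    ga[a.y_min : a.y_max, a.x_min : a.x_max] = True
    gb[b.y_min : b.y_max, b.x_min : b.x_max] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union


# ---------------------------------------------------------------------------
# IoU


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (box(0, 0, 10, 10), box(0, 0, 10, 10), 1.0),
        (box(0, 0, 10, 10), box(20, 20, 30, 30), 0.0),
        (box(0, 0, 10, 10), box(5, 0, 15, 10), 1 / 3),  # 50 / 150
        (box(0, 0, 10, 10), box(10, 0, 20, 10), 0.0),  # half-open: edge-adjacent
    ],
)
def test_iou_examples(a, b, expected):
    assert iou(a, b) == pytest.approx(expected)
    assert iou(a, b) == pytest.approx(iou_rasterized(a, b))


@given(boxes(), boxes())
def test_iou_symmetric_and_bounded(a, b):
    v = iou(a, b)
    assert 0.0 <= v <= 1.0
    assert v == pytest.approx(iou(b, a))
    assert iou(a, a) == 1.0


@given(boxes(), boxes())
def test_iou_matches_rasterized_oracle(a, b):
    assert iou(a, b) == pytest.approx(iou_rasterized(a, b))


# ---------------------------------------------------------------------------
# Filters


def test_edge_filter_removes_top_touching_boxes():
    dets = DetectionSet(
        [box(5, 0, 20, 30, 0.9), box(5, 3, 20, 30, 0.8), box(2, 0, 9, 9, 0.7), box(1, 12, 9, 30, 0.6)]
    )
    kept, removed = filter_edge_boxes(dets)
    assert removed == 2
    assert [b.y_min for b in kept.records] == [3, 12]


def test_edge_filter_identity_when_no_edge_boxes():
    dets = DetectionSet([box(5, 2, 20, 30, 0.9), box(1, 12, 9, 30, 0.6)])
    kept, removed = filter_edge_boxes(dets)
    assert removed == 0
    assert kept.records == dets.records


def test_edge_filter_optional_x_edge():
    dets = DetectionSet([box(0, 5, 20, 30, 0.9), box(5, 5, 20, 30, 0.8)])
    kept, removed = filter_edge_boxes(dets, include_x_edges=True)
    assert removed == 1 and kept.records[0].x_min == 5


def test_confidence_filter_boundary_is_kept():
    dets = DetectionSet([box(0, 1, 5, 5, c) for c in (0.29, 0.30, 0.95)])
    kept, removed = filter_low_confidence(dets, 0.30)
    assert removed == 1
    assert [b.confidence for b in kept.records] == [0.30, 0.95]


def test_confidence_filter_zero_threshold_is_identity():
    dets = DetectionSet([box(0, 1, 5, 5, c) for c in (0.0, 0.5, 1.0)])
    kept, removed = filter_low_confidence(dets, 0.0)
    assert removed == 0 and kept.records == dets.records


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_confidence_filter_matches_linear_scan(confs):
    dets = DetectionSet([box(0, 1, 5, 5, round(c, 6)) for c in confs])
    kept, removed = filter_low_confidence(dets, 0.5)
    expected = sum(1 for b in dets.records if b.confidence >= 0.5)
    assert len(kept) == expected
    assert removed == len(confs) - expected


@given(st.lists(boxes(), max_size=25))
def test_edge_and_confidence_filters_commute(bs):
    dets = DetectionSet(bs)
    a = filter_low_confidence(filter_edge_boxes(dets)[0], 0.4)[0]
    b = filter_edge_boxes(filter_low_confidence(dets, 0.4)[0])[0]
    assert a.records == b.records


# ---------------------------------------------------------------------------
# Deduplication


def test_dedup_keeps_highest_confidence_of_identical_pair():
    dets = DetectionSet([box(0, 1, 10, 10, 0.4), box(0, 1, 10, 10, 0.9)])
    out = deduplicate(dets)
    assert len(out) == 1 and out.records[0].confidence == 0.9


def test_dedup_keeps_disjoint_boxes():
    dets = DetectionSet([box(0, 1, 10, 10, 0.9), box(50, 50, 60, 60, 0.4)])
    assert len(deduplicate(dets)) == 2


def dedup_group_oracle(records, threshold):
    """Exhaustive pairwise-IoU grouping: visit by descending confidence and
    assign each box to the first kept box it overlaps; count the keepers."""
    order = sorted(range(len(records)), key=lambda i: (-records[i].confidence, i))
    keepers = []
    for i in order:
        if not any(
            iou(records[i], records[j]) > threshold
            and records[i].date == records[j].date
            and records[i].class_label == records[j].class_label
            for j in keepers
        ):
            keepers.append(i)
    return {records[i] for i in keepers}


def test_dedup_jittered_cluster_plus_far_box():
    base = box(20, 20, 60, 60, 0.95)
    cluster = [base] + [
        box(20 + d, 20 + d, 60 + d, 60 + d, 0.9 - 0.1 * k)
        for k, d in enumerate((1, 2, 3, 4), start=1)
    ]
    far = box(80, 80, 95, 95, 0.5)
    dets = DetectionSet(cluster + [far])
    out = deduplicate(dets, 0.5)
    assert len(out) == 2
    assert set(out.records) == dedup_group_oracle(dets.records, 0.5)


@given(st.lists(boxes(max_coord=30), max_size=12))
def test_dedup_matches_grouping_oracle(bs):
    dets = DetectionSet(bs)
    out = deduplicate(dets, 0.5)
    assert set(out.records) == dedup_group_oracle(bs, 0.5)


def test_dedup_separate_dates_not_merged():
    a = box(0, 1, 10, 10, 0.9, date=dt.date(2020, 4, 1))
    b = box(0, 1, 10, 10, 0.8, date=dt.date(2020, 4, 2))
    assert len(deduplicate(DetectionSet([a, b]))) == 2


# ---------------------------------------------------------------------------
# mAP


def ap_oracle(dets, truth, thr):
    """Independent AP oracle: naive greedy matching, explicit PR points,
    envelope integration on the distinct recall steps."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    matched = set()
    points = []  # (recall, precision) after each detection
    tp = 0
    for rank, i in enumerate(order, start=1):
        best, best_iou = None, 0.0
        for j, t in enumerate(truth):
            if j in matched or t.date != dets[i].date:
                continue
            v = iou(dets[i], t)
            if v > best_iou:
                best, best_iou = j, v
        if best is not None and best_iou >= thr:
            matched.add(best)
            tp += 1
        points.append((tp / len(truth), tp / rank))
    ap = 0.0
    prev_r = 0.0
    for r, _ in points:
        if r > prev_r:
            p_interp = max(p for rr, p in points if rr >= r)
            ap += (r - prev_r) * p_interp
            prev_r = r
    return ap


def test_map_perfect_detector_is_one():
    truth = DetectionSet([box(0, 1, 10, 10), box(30, 30, 50, 50)])
    dets = DetectionSet([box(0, 1, 10, 10, 0.9), box(30, 30, 50, 50, 0.9)])
    assert mean_average_precision(dets, truth, 0.5) == 1.0


def test_map_all_disjoint_is_zero():
    truth = DetectionSet([box(0, 1, 10, 10)])
    dets = DetectionSet([box(50, 50, 60, 60, 0.9)])
    assert mean_average_precision(dets, truth, 0.5) == 0.0


def test_map_hand_enumerated_example():
    # 3 truth boxes; detections by descending confidence: TP, FP, TP, TP.
    # PR points (1, 1/3), (1/2, 1/3), (2/3, 2/3), (3/4, 1); all-point AP
    # = 1/3*1 + 1/3*3/4 + 1/3*3/4 = 5/6.
    truth = DetectionSet([box(0, 1, 10, 10), box(30, 1, 40, 10), box(60, 1, 70, 10)])
    dets = DetectionSet(
        [
            box(0, 1, 10, 10, 0.9),
            box(80, 40, 95, 50, 0.8),
            box(30, 1, 40, 10, 0.7),
            box(60, 1, 70, 10, 0.6),
        ]
    )
    assert mean_average_precision(dets, truth, 0.5) == pytest.approx(5 / 6)
    assert ap_oracle(dets.records, truth.records, 0.5) == pytest.approx(5 / 6)


def test_map_empty_truth_raises():
    with pytest.raises(EmptyTruthError):
        mean_average_precision(DetectionSet([box(0, 1, 5, 5, 0.5)]), DetectionSet([]), 0.5)


@given(st.lists(boxes(max_coord=40), max_size=10), st.lists(boxes(max_coord=40), min_size=1, max_size=6))
def test_map_matches_enumeration_oracle(det_boxes, truth_boxes):
    dets = DetectionSet(det_boxes)
    truth = DetectionSet([BoundingBox(b.x_min, b.y_min, b.x_max, b.y_max, None, date=b.date) for b in truth_boxes])
    got = mean_average_precision(dets, truth, 0.5)
    assert got == pytest.approx(ap_oracle(dets.records, truth.records, 0.5))


@given(st.lists(boxes(max_coord=40), min_size=1, max_size=10), st.lists(boxes(max_coord=40), min_size=1, max_size=6))
def test_map_stricter_iou_never_higher(det_boxes, truth_boxes):
    dets = DetectionSet(det_boxes)
    truth = DetectionSet([BoundingBox(b.x_min, b.y_min, b.x_max, b.y_max, None, date=b.date) for b in truth_boxes])
    assert mean_average_precision(dets, truth, 0.75) <= mean_average_precision(dets, truth, 0.5) + 1e-12


def test_map_invariant_to_monotone_confidence_transform():
    truth = DetectionSet([box(0, 1, 10, 10), box(30, 1, 40, 10), box(60, 1, 70, 10)])
    dets = DetectionSet(
        [box(0, 1, 10, 10, 0.9), box(80, 40, 95, 50, 0.8), box(30, 1, 40, 10, 0.7), box(60, 1, 70, 10, 0.6)]
    )
    squashed = DetectionSet(
        [BoundingBox(b.x_min, b.y_min, b.x_max, b.y_max, round(b.confidence**3, 9), date=b.date) for b in dets.records]
    )
    assert mean_average_precision(dets, truth, 0.5) == pytest.approx(
        mean_average_precision(squashed, truth, 0.5)
    )


# ---------------------------------------------------------------------------
# I/O round trips


def test_csv_round_trip(tmp_path):
    dets = DetectionSet(
        [box(0, 1, 10, 10, 0.875, tree_id="t1"), box(3, 0, 9, 12, None, tree_id="t2")],
        image_size=(100, 100),
    )
    path = tmp_path / "dets.csv"
    write_detections_csv(dets, path)
    back = read_detections_csv(path, image_size=(100, 100))
    assert back.records == dets.records


def test_coco_round_trip(tmp_path):
    dets = DetectionSet(
        [box(0, 1, 10, 10, 0.875, tree_id="t1"), box(3, 2, 9, 12, 0.5, tree_id="t2")],
        image_size=(100, 100),
    )
    path = tmp_path / "dets.json"
    write_coco_json(dets, path)
    back = read_coco_json(path)
    assert back.records == dets.records
    assert back.image_size == (100, 100)
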