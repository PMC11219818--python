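"""Evaluation stack: IoU, NMS, matching, PR curves, AP, F1, mAP."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikedet.metrics import (
    DetectionBox, GroundTruthBox, IOU_GRID_COCO, PRCurve, average_precision,
    evaluate, f1_score, iou, load_yolo_boxes, match_detections, nms,
    precision_recall, save_yolo_boxes,
)


def D(x0, y0, x1, y1, s=1.0):
    return DetectionBox(x0, y0, x1, y1, score=s)


def G(x0, y0, x1, y1):
    return GroundTruthBox(x0, y0, x1, y1)


class TestIoU:
    def test_identical_boxes(self):
        assert iou(D(0, 0, 2, 2), D(0, 0, 2, 2)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(D(0, 0, 1, 1), D(5, 5, 6, 6)) == 0.0

    def test_partial_overlap_hand_computed(self):
        # intersection 2, union 6
        assert iou(D(0, 0, 2, 2), D(1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = np.sort(rng.uniform(0, 10, 4))
            b = np.sort(rng.uniform(0, 10, 4))
            ba = (a[0], a[1], a[2] + 1, a[3] + 1)
            bb = (b[0], b[1], b[2] + 1, b[3] + 1)
            assert iou(ba, bb) == pytest.approx(iou(bb, ba))

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 2), (0, 0, 1, 1))


class TestNMS:
    def test_single_box_survives(self):
        b = D(0, 0, 2, 2, 0.5)
        assert nms([b], 0.5) == [b]

    def test_duplicate_suppressed(self):
        hi, lo = D(0, 0, 2, 2, 0.9), D(0, 0, 2, 2, 0.8)
        assert nms([lo, hi], 0.5) == [hi]

    def test_greedy_trace(self):
        # A overlaps B (IoU 0.6), C disjoint, scores A>B>C
        a = D(0, 0, 10, 10, 0.9)
        b = D(0, 0, 10, 6, 0.8)  # IoU with a = 0.6
        c = D(50, 50, 60, 60, 0.7)
        assert iou(a, b) == pytest.approx(0.6)
        assert nms([a, b, c], 0.5) == [a, c]

    def test_idempotent(self, rng):
        boxes = [D(x, y, x + w, y + h, s) for x, y, w, h, s in
                 rng.uniform(1, 20, size=(30, 5))]
        once = nms(boxes, 0.5)
        assert nms(once, 0.5) == once

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            nms([], 1.5)


class TestMatching:
    def test_perfect_detections(self):
        gts = [G(0, 0, 2, 2), G(5, 5, 7, 7)]
        dets = [D(0, 0, 2, 2, 0.9), D(5, 5, 7, 7, 0.8)]
        flags, fn = match_detections(dets, gts, 0.5)
        assert flags == [True, True] and fn == 0

    def test_one_to_one_constraint(self):
        gts = [G(0, 0, 2, 2)]
        dets = [D(0, 0, 2, 2, 0.9), D(0, 0, 2, 2, 0.8)]
        flags, fn = match_detections(dets, gts, 0.5)
        assert flags == [True, False] and fn == 0

    def test_trace_with_miss(self):
        gts = [G(0, 0, 2, 2), G(10, 10, 12, 12), G(20, 20, 22, 22)]
        dets = [D(0, 0, 2, 2, 0.9),       # hit
                D(40, 40, 42, 42, 0.8),   # miss
                D(10, 10, 12, 12, 0.7)]   # hit
        flags, fn = match_detections(dets, gts, 0.5)
        assert flags == [True, False, True] and fn == 1


class TestPrecisionRecall:
    def test_single_tp(self):
        c = precision_recall([True], 1)
        assert c.precision == [1.0] and c.recall == [1.0]

    def test_cumulative_arithmetic(self):
        c = precision_recall([True, False], 2)
        assert c.precision == [1.0, 0.5]
        assert c.recall == [0.5, 0.5]

    def test_empty_flags(self):
        c = precision_recall([], 3)
        assert c.precision == [] and c.recall == []

    def test_zero_gt_warns_not_raises(self):
        c = precision_recall([False, False], 0)
        assert c.recall == [0.0, 0.0]
        assert c.warnings


def _brute_force_ap(flags, n_gt):
    """Step-area oracle: envelope integral computed point by point."""
    if n_gt == 0 or not flags:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum([not f for f in flags])
    prec = tp / (tp + fp)
    rec = tp / n_gt
    area = 0.0
    prev_r = 0.0
    for i in range(len(flags)):
        if rec[i] > prev_r:
            envelope = max(prec[i:])  # best precision at recall >= rec[i]
            area += (rec[i] - prev_r) * envelope
            prev_r = rec[i]
    return area


class TestAveragePrecision:
    def test_perfect_detector(self):
        assert average_precision(precision_recall([True] * 4, 4)) == 1.0

    def test_no_detections(self):
        assert average_precision(PRCurve()) == 0.0

    def test_hand_computed_envelope(self):
        # flags [TP, FP, TP] with 2 gts: 0.5*1.0 + 0.5*(2/3)
        curve = precision_recall([True, False, True], 2)
        assert average_precision(curve) == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_matches_brute_force_oracle_on_200_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_gt = int(rng.integers(1, 11))
            n_det = int(rng.integers(0, 11))
            hits = min(n_gt, n_det)
            flags = list(rng.random(n_det) < 0.5)
            while sum(flags) > n_gt:
                flags[flags.index(True)] = False
            ap = average_precision(precision_recall(flags, n_gt))
            assert ap == pytest.approx(_brute_force_ap(flags, n_gt), abs=1e-12)

    def test_score_scale_invariance(self, rng):
        """AP depends only on ranks: uniform positive rescale changes nothing."""
        gts = {0: [G(i * 10, 0, i * 10 + 5, 5) for i in range(5)]}
        dets = [DetectionBox(i * 10, 0, i * 10 + 5, 5, score=s)
                for i, s in enumerate(rng.uniform(0.1, 0.9, 5))]
        dets += [DetectionBox(100 + i * 10, 0, 105 + i * 10, 5,
                              score=float(s))
                 for i, s in enumerate(rng.uniform(0.1, 0.9, 3))]
        r1 = evaluate({0: dets}, gts)
        scaled = [DetectionBox(d.x_min, d.y_min, d.x_max, d.y_max,
                               score=d.score * 0.37, class_id=d.class_id)
                  for d in dets]
        r2 = evaluate({0: scaled}, gts, conf_threshold=0.0)
        assert r1.mAP50 == pytest.approx(r2.mAP50, abs=1e-9)


class TestF1:
    @pytest.mark.parametrize("p,r,expected", [
        (80.81, 75.35, 77.98),   # published baseline row
        (83.65, 77.54, 80.48),   # published SimConv-head row
    ])
    def test_published_rows_reproduce(self, p, r, expected):
        assert f1_score(p, r) == pytest.approx(expected, abs=0.005)

    def test_zero_limit(self):
        assert f1_score(0.0, 0.0) == 0.0

    def test_symmetry_and_bounds(self, rng):
        for p, r in rng.uniform(1, 99, size=(50, 2)):
            f = f1_score(p, r)
            assert f == pytest.approx(f1_score(r, p))
            assert min(p, r) <= f <= max(p, r)


class TestEvaluate:
    def _perfect(self):
        gts = {i: [G(0, 0, 10, 10), G(20, 20, 40, 45)] for i in range(3)}
        dets = {i: [D(0, 0, 10, 10, 0.9), D(20, 20, 40, 45, 0.8)]
                for i in range(3)}
        return dets, gts

    def test_iou_grid_has_ten_thresholds(self):
        assert len(IOU_GRID_COCO) == 10
        assert IOU_GRID_COCO[0] == 0.5 and IOU_GRID_COCO[-1] == 0.95

    def test_single_class_map50_equals_ap(self):
        dets, gts = self._perfect()
        r = evaluate(dets, gts)
        assert r.mAP50 == r.AP

    def test_perfect_geometry_maxes_all_thresholds(self):
        dets, gts = self._perfect()
        r = evaluate(dets, gts)
        assert r.mAP5095 == pytest.approx(100.0)
        assert r.P == pytest.approx(100.0) and r.R == pytest.approx(100.0)

    def test_map5095_never_exceeds_map50(self, rng):
        gts = {0: [G(i * 20, 0, i * 20 + 10, 12) for i in range(6)]}
        dets = {0: [D(i * 20 + rng.uniform(0, 3), rng.uniform(0, 3),
                      i * 20 + 10 + rng.uniform(0, 3), 12 + rng.uniform(0, 3),
                      s=float(rng.uniform(0.3, 1)))
                    for i in range(6)]}
        r = evaluate(dets, gts)
        assert r.mAP5095 <= r.mAP50 + 1e-9

    def test_empty_ground_truth_warns(self):
        with pytest.warns(UserWarning):
            r = evaluate({0: [D(0, 0, 1, 1, 0.5)]}, {0: []})
        assert r.mAP50 == 0.0 and r.warnings


class TestYoloIO:
    def test_known_normalization(self, tmp_path):
        p = tmp_path / "a.txt"
        save_yolo_boxes(p, [G(0, 0, 176, 176)], 352)
        assert p.read_text().split() == ["0", "0.250000", "0.250000",
                                         "0.500000", "0.500000"]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("")
        assert load_yolo_boxes(p, 352) == []

    def test_roundtrip_100_random_boxes(self, tmp_path, rng):
        size = 352
        boxes = []
        for _ in range(100):
            x0, y0 = rng.uniform(0, 300, 2)
            w, h = rng.uniform(5, 50, 2)
            boxes.append(G(x0, y0, min(x0 + w, size), min(y0 + h, size)))
        p = tmp_path / "r.txt"
        save_yolo_boxes(p, boxes, size)
        back = load_yolo_boxes(p, size)
        for a, b in zip(boxes, back):
            for attr in ("x_min", "y_min", "x_max", "y_max"):
                assert abs(getattr(a, attr) - getattr(b, attr)) < 1e-6 * size

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2 0.2\n0 oops 0.5 0.2 0.2\n")
        with pytest.raises(ValueError, match=":2"):
            load_yolo_boxes(p, 352)


@given(st.lists(st.booleans(), max_size=12), st.integers(1, 12))
@settings(max_examples=80, deadline=None)
def test_ap_oracle_equivalence_property(flags, n_gt):
    flags = flags[:]
    while sum(flags) > n_gt:
        flags[flags.index(True)] = False
    ap = average_precision(precision_recall(flags, n_gt))
    assert ap == pytest.approx(_brute_force_ap(flags, n_gt), abs=1e-12)
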