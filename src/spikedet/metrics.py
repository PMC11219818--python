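"""Detection evaluation: IoU, NMS, greedy matching, P/R, AP, F1, mAP.

Conventions follow the standard single-class wheat-spike protocol:

* precision P = TP / (TP + FP), recall R = TP / (TP + FN), cumulated down
  the score-sorted detection list;
* AP is the area under the precision-envelope-interpolated PR curve
  (all-points interpolation; an 11-point variant is available);
* F1 = 2PR / (P + R);
* mAP@0.5 averages AP over classes at IoU 0.5 (equal to AP for one class);
  mAP@.5:.95 additionally averages over the ten IoU thresholds
  0.50, 0.55, ..., 0.95.

Results are reported as percentages (matching the field's tables);
internal arithmetic is in fractions.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "DetectionBox", "GroundTruthBox", "PRCurve", "EvalResult",
    "iou", "nms", "match_detections", "precision_recall",
    "average_precision", "f1_score", "evaluate", "IOU_GRID_COCO",
    "load_yolo_boxes", "save_yolo_boxes", "load_coco_json",
]

IOU_GRID_COCO = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))  # 10 thresholds


@dataclass
class DetectionBox:
    """Scored axis-aligned box in pixel coordinates (closed real intervals)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float = 1.0
    class_id: int = 0

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple:
        return ((self.x_min + self.x_max) / 2, (self.y_min + self.y_max) / 2)


@dataclass
class GroundTruthBox:
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_id: int = 0
    matched: bool = False

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


@dataclass
class PRCurve:
    """Cumulative precision/recall down the score-sorted detection list."""

    scores: list = field(default_factory=list)
    precision: list = field(default_factory=list)
    recall: list = field(default_factory=list)
    n_gt: int = 0
    warnings: list = field(default_factory=list)


@dataclass
class EvalResult:
    """Percent-scale summary for one model on one split."""

    P: float = 0.0
    R: float = 0.0
    AP: float = 0.0
    F1: float = 0.0
    mAP50: float = 0.0
    mAP5095: float = 0.0
    num_classes: int = 1
    warnings: list = field(default_factory=list)

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["P", "R", "AP", "F1", "mAP50", "mAP5095", "num_classes"])
            w.writerow([f"{self.P:.4f}", f"{self.R:.4f}", f"{self.AP:.4f}",
                        f"{self.F1:.4f}", f"{self.mAP50:.4f}",
                        f"{self.mAP5095:.4f}", self.num_classes])


def iou(a, b) -> float:
    """Intersection-over-union of two axis-aligned boxes; symmetric."""
    ax0, ay0, ax1, ay1 = _coords(a)
    bx0, by0, bx1, by1 = _coords(b)
    if ax1 <= ax0 or ay1 <= ay0 or bx1 <= bx0 or by1 <= by0:
        raise ValueError("degenerate box passed to iou")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return float(inter / union)


def _coords(b) -> tuple:
    if hasattr(b, "x_min"):
        return b.x_min, b.y_min, b.x_max, b.y_max
    return tuple(float(v) for v in b)


def nms(boxes: list, iou_threshold: float = 0.45) -> list:
    """Greedy non-maximum suppression by descending score; idempotent."""
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must be in (0, 1)")
    order = sorted(boxes, key=lambda b: -b.score)
    keep: list = []
    for cand in order:
        if all(iou(cand, k) < iou_threshold for k in keep
               if k.class_id == cand.class_id):
            keep.append(cand)
    return keep


def match_detections(dets: list, gts: list, iou_threshold: float = 0.5):
    """Greedy one-to-one matching by descending detection confidence.

    Each detection claims the highest-IoU still-unmatched ground truth of
    its class with IoU >= threshold (TP); otherwise it is an FP.  Returns
    ``(flags, fn)`` where ``flags[i]`` is True iff the i-th detection of
    the score-sorted list is a TP, and ``fn`` counts unmatched ground
    truths.  IoU ties break on ground-truth index for determinism.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    taken = [False] * len(gts)
    flags = []
    for i in order:
        d = dets[i]
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if taken[j] or g.class_id != d.class_id:
                continue
            v = iou(d, g)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags, taken.count(False)


def precision_recall(flags: list, n_gt: int, scores: list | None = None) -> PRCurve:
    """Cumulative P/R down a score-sorted TP/FP flag list."""
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    curve = PRCurve(n_gt=n_gt)
    if n_gt == 0 and flags:
        curve.warnings.append("no ground truths: recall reported as 0")
    tp = fp = 0
    for i, f in enumerate(flags):
        tp += bool(f)
        fp += not f
        curve.precision.append(tp / (tp + fp))
        curve.recall.append(tp / n_gt if n_gt > 0 else 0.0)
        curve.scores.append(scores[i] if scores is not None else None)
    return curve


def average_precision(curve: PRCurve, interpolation: str = "all") -> float:
    """Area under the precision-envelope-interpolated PR curve, in [0, 1].

    ``interpolation="all"`` integrates the monotone precision envelope over
    every recall step (area under the PR curve); ``"11point"`` averages the
    envelope at recalls 0, 0.1, ..., 1.0.
    """
    if not curve.precision:
        return 0.0
    r = np.concatenate([[0.0], np.asarray(curve.recall, dtype=np.float64), [1.0]])
    p = np.concatenate([[1.0], np.asarray(curve.precision, dtype=np.float64), [0.0]])
    # monotone non-increasing precision envelope, right to left
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    if interpolation == "11point":
        grid = np.linspace(0, 1, 11)
        # envelope value at the smallest recall >= g (0 beyond max recall)
        vals = []
        for g in grid:
            idx = np.searchsorted(r, g, side="left")
            vals.append(p[idx] if idx < len(p) else 0.0)
        return float(np.mean(vals))
    if interpolation != "all":
        raise ValueError("interpolation must be 'all' or '11point'")
    steps = np.nonzero(np.diff(r) > 0)[0]
    return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))


def f1_score(P: float, R: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when P + R = 0.  Works on any scale."""
    if P < 0 or R < 0:
        raise ValueError("P and R must be nonnegative")
    if P + R == 0:
        return 0.0
    return 2.0 * P * R / (P + R)


def _ap_at_threshold(dets_per_image: dict, gts_per_image: dict,
                     thr: float, class_id: int) -> float:
    """Pooled AP for one class at one IoU threshold across all images."""
    records = []  # (score, is_tp)
    n_gt = 0
    for img_id, gts in gts_per_image.items():
        gts_c = [g for g in gts if g.class_id == class_id]
        n_gt += len(gts_c)
        dets_c = [d for d in dets_per_image.get(img_id, [])
                  if d.class_id == class_id]
        flags, _ = match_detections(dets_c, gts_c, thr)
        order = sorted(dets_c, key=lambda d: -d.score)
        records += [(d.score, f) for d, f in zip(order, flags)]
    for img_id, dets in dets_per_image.items():
        if img_id not in gts_per_image:
            records += [(d.score, False) for d in dets if d.class_id == class_id]
    if n_gt == 0:
        return 0.0
    records.sort(key=lambda t: -t[0])
    curve = precision_recall([f for _, f in records], n_gt,
                             scores=[s for s, _ in records])
    return average_precision(curve)


def evaluate(dets_per_image: dict, gts_per_image: dict,
             iou_grid=IOU_GRID_COCO, conf_threshold: float = 0.25,
             num_classes: int = 1) -> EvalResult:
    """Full evaluation of detections against ground truths over a split.

    ``dets_per_image``/``gts_per_image`` map image ids to box lists.  P, R
    and F1 are reported at ``conf_threshold``; AP and the mAPs use the full
    score-sorted curves.  All outputs are percentages.
    """
    result = EvalResult(num_classes=num_classes)
    total_gt = sum(len(v) for v in gts_per_image.values())
    if total_gt == 0:
        result.warnings.append("empty ground-truth set: all metrics zero")
        warnings.warn("evaluate(): empty ground-truth set", stacklevel=2)
        return result
    classes = range(num_classes)

    ap50 = [_ap_at_threshold(dets_per_image, gts_per_image, 0.5, c)
            for c in classes]
    result.mAP50 = 100.0 * float(np.mean(ap50))
    result.AP = result.mAP50

    grid = list(iou_grid)
    per_thr = [np.mean([_ap_at_threshold(dets_per_image, gts_per_image, t, c)
                        for c in classes]) for t in grid]
    result.mAP5095 = 100.0 * float(np.mean(per_thr))

    # operating-point P/R at IoU 0.5 and the confidence threshold
    tp = fp = fn = 0
    for img_id, gts in gts_per_image.items():
        dets = [d for d in dets_per_image.get(img_id, [])
                if d.score >= conf_threshold]
        flags, miss = match_detections(dets, gts, 0.5)
        tp += sum(flags)
        fp += len(flags) - sum(flags)
        fn += miss
    for img_id, dets in dets_per_image.items():
        if img_id not in gts_per_image:
            fp += sum(d.score >= conf_threshold for d in dets)
    result.P = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    result.R = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    result.F1 = f1_score(result.P, result.R)
    return result


# -- I/O ------------------------------------------------------------------

def load_yolo_boxes(path, image_size, with_scores: bool = False,
                    kind: str = "gt") -> list:
    """Read normalized ``class cx cy w h [score]`` lines into pixel boxes."""
    w_img, h_img = (image_size, image_size) if np.isscalar(image_size) else image_size
    boxes = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        want = 6 if with_scores else 5
        if len(parts) != want:
            raise ValueError(f"{path}:{ln}: expected {want} fields, got {len(parts)}")
        try:
            cid = int(parts[0])
            cx, cy, bw, bh = (float(v) for v in parts[1:5])
            score = float(parts[5]) if with_scores else 1.0
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: malformed number ({e})") from None
        x0, y0 = (cx - bw / 2) * w_img, (cy - bh / 2) * h_img
        x1, y1 = (cx + bw / 2) * w_img, (cy + bh / 2) * h_img
        if kind == "gt":
            boxes.append(GroundTruthBox(x0, y0, x1, y1, class_id=cid))
        else:
            boxes.append(DetectionBox(x0, y0, x1, y1, score=score, class_id=cid))
    return boxes


def save_yolo_boxes(path, boxes, image_size, with_scores: bool = False):
    w_img, h_img = (image_size, image_size) if np.isscalar(image_size) else image_size
    lines = []
    for b in boxes:
        cx = (b.x_min + b.x_max) / 2 / w_img
        cy = (b.y_min + b.y_max) / 2 / h_img
        bw = (b.x_max - b.x_min) / w_img
        bh = (b.y_max - b.y_min) / h_img
        line = f"{b.class_id} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}"
        if with_scores:
            line += f" {b.score:.6f}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_coco_json(path, kind: str = "gt") -> dict:
    """Read a COCO-dialect JSON into ``{image_id: [boxes]}`` (xywh -> corners)."""
    doc = json.loads(Path(path).read_text())
    anns = doc["annotations"] if isinstance(doc, dict) else doc
    out: dict = {}
    for a in anns:
        x, y, w, h = a["bbox"]
        img = a["image_id"]
        cid = int(a.get("category_id", 0))
        if kind == "gt":
            box = GroundTruthBox(x, y, x + w, y + h, class_id=cid)
        else:
            box = DetectionBox(x, y, x + w, y + h,
                               score=float(a.get("score", 1.0)), class_id=cid)
        out.setdefault(img, []).append(box)
    return out
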