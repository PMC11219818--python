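"""Score a set of detections against ground truth with the full metric stack.

Walks through the standard single-class protocol: greedy IoU matching at
descending confidence, the cumulative precision/recall curve, AP as the
area under its interpolated envelope, F1 at the operating point, and the
two mAP summaries (IoU 0.5, and averaged over IoU 0.50..0.95).
"""

from spikedet.metrics import (
    DetectionBox, GroundTruthBox, average_precision, evaluate, f1_score,
    match_detections, precision_recall,
)

# two images, five spikes, six detections (one duplicate, one false alarm,
# and one spike with no detection at all)
gts = {
    "img0": [GroundTruthBox(10, 10, 50, 40), GroundTruthBox(70, 20, 120, 60),
             GroundTruthBox(30, 70, 80, 100)],
    "img1": [GroundTruthBox(5, 5, 45, 30), GroundTruthBox(60, 50, 110, 90)],
}
dets = {
    "img0": [DetectionBox(12, 11, 51, 41, score=0.92),
             DetectionBox(69, 21, 119, 59, score=0.88),
             DetectionBox(14, 12, 52, 42, score=0.55),   # duplicate
             DetectionBox(31, 71, 79, 99, score=0.80)],
    "img1": [DetectionBox(6, 6, 44, 31, score=0.90),
             DetectionBox(200, 200, 240, 230, score=0.40)],  # false alarm
}

flags, fn = match_detections(dets["img0"], gts["img0"], iou_threshold=0.5)
print(f"img0 matching: TP/FP flags {flags}, missed ground truths {fn}")

curve = precision_recall(flags, n_gt=len(gts["img0"]))
print(f"img0 PR points: P={['%.2f' % p for p in curve.precision]} "
      f"R={['%.2f' % r for r in curve.recall]}")
print(f"img0 AP (area under interpolated PR curve): "
      f"{average_precision(curve):.4f}")

result = evaluate(dets, gts, conf_threshold=0.25)
print(f"\nsplit-level: P={result.P:.2f}% R={result.R:.2f}% "
      f"F1={result.F1:.2f}% mAP@0.5={result.mAP50:.2f}% "
      f"mAP@.5:.95={result.mAP5095:.2f}%")
print("(the duplicate and the false alarm cost precision, the undetected "
      f"spike costs recall; F1 = 2PR/(P+R) = {f1_score(result.P, result.R):.2f}%)")
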