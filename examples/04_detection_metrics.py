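"""The detection-metric suite on a tiny hand-built scenario.

Two images, two classes: one correct detection, one misclassified, one miss.
Prints the confusion counts, P/R, AP at IoU 0.5 and the mAP pair.
"""

from lesiondet.boxgeom import Box
from lesiondet.metrics import (GroundTruth, evaluate_detections,
                               match_detections)
from lesiondet.model import Detection

gts = [
    [GroundTruth(Box(10, 10, 30, 30), 0), GroundTruth(Box(40, 40, 55, 60), 1)],
    [GroundTruth(Box(5, 5, 25, 20), 0)],
]
dets = [
    [Detection(Box(11, 11, 31, 29), 0, 0.92),      # hit on class 0
     Detection(Box(41, 39, 56, 61), 0, 0.80)],     # wrong class -> FP + FN
    [],                                            # missed lesion -> FN
]

counts, matches = match_detections(dets[0], gts[0], iou_thr=0.5)
print(f"image 0 box-level counts: TP={counts.tp} FP={counts.fp} FN={counts.fn}")

report = evaluate_detections(dets, gts, num_classes=2)
print(report.to_frame().round(3).to_string())
print(f"mAP50 = {report.map50:.3f}, mAP50-95 = {report.map50_95:.3f}")
# The ALL-LESIONS row collapses class labels: the wrong-class detection still
# localizes a lesion, so class-agnostic recall exceeds the per-class values.
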