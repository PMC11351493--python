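"""Detection evaluation: confusion counting, P/R/ACC/specificity, AP and mAP.

Box-level matching is the standard greedy scheme: detections are processed
in descending confidence and each claims the highest-IoU unmatched
ground-truth box of its own class with IoU ≥ threshold (TP), otherwise it is
a false positive; unmatched ground truths are false negatives.

True negatives are undefined for box-level detection, so accuracy and
specificity are computed at image level: for every (image, class) pair,
predicted-present versus truly-present fills the 2×2 table.

AP is the all-point-interpolated area under the precision–recall curve (the
precision envelope is made monotone non-increasing before integration);
mAP is the unweighted mean over classes, and mAP50–95 additionally averages
over IoU thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxgeom import Box, iou_xyxy

__all__ = [
    "ConfusionCounts",
    "GroundTruth",
    "PRCurve",
    "EvalReport",
    "match_detections",
    "precision",
    "recall",
    "accuracy",
    "specificity",
    "average_precision",
    "mean_ap",
    "ap_at_threshold",
    "map50",
    "map50_95",
    "image_level_counts",
    "evaluate_detections",
    "aggregate_reports",
    "IOU_SWEEP",
]

IOU_SWEEP = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class GroundTruth:
    box: Box
    class_id: int


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "recall")


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.tp + c.tn + c.fn + c.fp, "accuracy")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def match_detections(dets, gts, iou_thr: float):
    """Greedy same-class matching on one image.

    Returns (ConfusionCounts with tn=0, list of (det_index, gt_index)).
    """
    if not 0.0 < iou_thr <= 1.0:
        raise ValueError(f"IoU threshold must lie in (0, 1], got {iou_thr}")
    dets = list(dets)
    gts = list(gts)
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    gt_used = [False] * len(gts)
    gt_arr = np.array([g.box.as_array() for g in gts]).reshape(-1, 4)
    matches = []
    tp = fp = 0
    for di in order:
        d = dets[di]
        best_iou, best_gi = 0.0, -1
        for gi, g in enumerate(gts):
            if gt_used[gi] or g.class_id != d.class_id:
                continue
            v = float(iou_xyxy(d.box.as_array(), gt_arr[gi]))
            if v >= iou_thr and v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi >= 0:
            gt_used[best_gi] = True
            matches.append((di, best_gi))
            tp += 1
        else:
            fp += 1
    fn = gt_used.count(False)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn), matches


@dataclass
class PRCurve:
    """Precision–recall points from a descending-confidence sweep."""

    recalls: np.ndarray
    precisions: np.ndarray

    @classmethod
    def from_flags(cls, confidences, tp_flags, num_gt: int) -> "PRCurve":
        conf = np.asarray(confidences, dtype=float)
        tp = np.asarray(tp_flags, dtype=float)
        order = np.argsort(-conf, kind="stable")
        tp = tp[order]
        cum_tp = np.cumsum(tp)
        cum_fp = np.cumsum(1.0 - tp)
        prec = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
        rec = cum_tp / num_gt if num_gt > 0 else np.zeros_like(cum_tp)
        return cls(rec, prec)


def average_precision(curve: PRCurve) -> float:
    """All-point-interpolated area under the PR curve."""
    if curve.recalls.size == 0:
        return 0.0
    rec = np.concatenate([[0.0], curve.recalls, [curve.recalls[-1]]])
    prec = np.concatenate([[1.0], curve.precisions, [0.0]])
    # monotone non-increasing precision envelope
    prec = np.maximum.accumulate(prec[::-1])[::-1]
    return float(np.sum(np.diff(rec) * prec[1:]))


def mean_ap(per_class_ap) -> float:
    aps = list(per_class_ap)
    if not aps:
        raise ValueError("need at least one class AP")
    return float(np.mean(aps))


def _sweep_flags(dets_by_image, gts_by_image, iou_thr, class_id):
    """Global confidence/TP-flag lists for one class (or all, class-agnostic)."""
    confs, flags = [], []
    num_gt = 0
    for dets, gts in zip(dets_by_image, gts_by_image):
        if class_id is None:
            # class-agnostic: collapse labels to one class
            dets = [_relabel(d, 0) for d in dets]
            gts = [GroundTruth(g.box, 0) for g in gts]
        else:
            dets = [d for d in dets if d.class_id == class_id]
            gts = [g for g in gts if g.class_id == class_id]
        num_gt += len(gts)
        _, matches = match_detections(dets, gts, iou_thr)
        matched = {di for di, _ in matches}
        for di, d in enumerate(dets):
            confs.append(d.confidence)
            flags.append(1.0 if di in matched else 0.0)
    return confs, flags, num_gt


def _relabel(d, cid):
    from .model import Detection
    return Detection(d.box, cid, d.confidence)


def ap_at_threshold(dets_by_image, gts_by_image, iou_thr: float,
                    class_id=None) -> float:
    confs, flags, num_gt = _sweep_flags(dets_by_image, gts_by_image, iou_thr, class_id)
    if num_gt == 0:
        return 0.0
    return average_precision(PRCurve.from_flags(confs, flags, num_gt))


def _present_classes(gts_by_image) -> list[int]:
    return sorted({g.class_id for gts in gts_by_image for g in gts})


def map50(dets_by_image, gts_by_image) -> float:
    classes = _present_classes(gts_by_image)
    return mean_ap([ap_at_threshold(dets_by_image, gts_by_image, 0.5, c)
                    for c in classes])


def map50_95(dets_by_image, gts_by_image) -> float:
    classes = _present_classes(gts_by_image)
    per_class = []
    for c in classes:
        per_class.append(np.mean([ap_at_threshold(dets_by_image, gts_by_image, t, c)
                                  for t in IOU_SWEEP]))
    return mean_ap(per_class)


def image_level_counts(dets_by_image, labels_by_image, num_classes: int):
    """Per-class presence/absence confusion over images.

    ``labels_by_image`` is a list of sets (or iterables) of truly-present
    class ids per image; detections are assumed already confidence-filtered.
    """
    counts = {c: ConfusionCounts() for c in range(num_classes)}
    for dets, labels in zip(dets_by_image, labels_by_image):
        pred = {d.class_id for d in dets}
        true = set(labels)
        for c in range(num_classes):
            if c in pred and c in true:
                counts[c].tp += 1
            elif c in pred:
                counts[c].fp += 1
            elif c in true:
                counts[c].fn += 1
            else:
                counts[c].tn += 1
    return counts


@dataclass
class EvalReport:
    """Per-class and all-lesion detection metrics for one evaluation split."""

    per_class: dict = field(default_factory=dict)   # class_id -> metric dict
    all_lesions: dict = field(default_factory=dict)
    map50: float = 0.0
    map50_95: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": "ALL-LESIONS", **self.all_lesions}]
        for c in sorted(self.per_class):
            rows.append({"class": f"class_{c}", **self.per_class[c]})
        return pd.DataFrame(rows).set_index("class")


def evaluate_detections(dets_by_image, gts_by_image, num_classes: int) -> EvalReport:
    """Full report: per-class and class-agnostic P/R/ACC/specificity/AP."""
    classes = list(range(num_classes))
    report = EvalReport()
    labels_by_image = [{g.class_id for g in gts} for gts in gts_by_image]
    img_counts = image_level_counts(dets_by_image, labels_by_image, num_classes)
    present = _present_classes(gts_by_image)
    for c in classes:
        box_counts = ConfusionCounts()
        for dets, gts in zip(dets_by_image, gts_by_image):
            cc, _ = match_detections([d for d in dets if d.class_id == c],
                                     [g for g in gts if g.class_id == c], 0.5)
            box_counts = box_counts + cc
        ap50 = ap_at_threshold(dets_by_image, gts_by_image, 0.5, c)
        ap_sweep = float(np.mean([ap_at_threshold(dets_by_image, gts_by_image, t, c)
                                  for t in IOU_SWEEP]))
        report.per_class[c] = {
            "precision": precision(box_counts),
            "recall": recall(box_counts),
            "accuracy": accuracy(img_counts[c]),
            "specificity": specificity(img_counts[c]),
            "ap50": ap50,
            "ap50_95": ap_sweep,
        }
    # class-agnostic row
    agg_box = ConfusionCounts()
    for dets, gts in zip(dets_by_image, gts_by_image):
        cc, _ = match_detections([_relabel(d, 0) for d in dets],
                                 [GroundTruth(g.box, 0) for g in gts], 0.5)
        agg_box = agg_box + cc
    any_labels = [({0} if labels else set()) for labels in labels_by_image]
    any_dets = [[_relabel(d, 0) for d in dets] for dets in dets_by_image]
    img_any = image_level_counts(any_dets, any_labels, 1)[0]
    report.all_lesions = {
        "precision": precision(agg_box),
        "recall": recall(agg_box),
        "accuracy": accuracy(img_any),
        "specificity": specificity(img_any),
        "ap50": ap_at_threshold(dets_by_image, gts_by_image, 0.5, None),
        "ap50_95": float(np.mean([ap_at_threshold(dets_by_image, gts_by_image, t, None)
                                  for t in IOU_SWEEP])),
    }
    if present:
        report.map50 = mean_ap([report.per_class[c]["ap50"] for c in present])
        report.map50_95 = mean_ap([report.per_class[c]["ap50_95"] for c in present])
    return report


def aggregate_reports(reports: list[EvalReport]) -> pd.DataFrame:
    """Across-fold mean ± standard deviation for every metric row."""
    frames = [r.to_frame() for r in reports]
    stacked = pd.concat(frames, keys=range(len(frames)), names=["fold"])
    mean = stacked.groupby(level=1, sort=False).mean()
    sd = stacked.groupby(level=1, sort=False).std(ddof=1).fillna(0.0)
    out = mean.copy()
    for col in mean.columns:
        out[col + "_sd"] = sd[col]
    out["map50"] = np.mean([r.map50 for r in reports])
    out["map50_95"] = np.mean([r.map50_95 for r in reports])
    return out
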