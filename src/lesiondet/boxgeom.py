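"""Axis-aligned box geometry: IoU and the minimum-point-distance IoU loss.

MPDIoU augments plain intersection-over-union with squared distances between
the two boxes' top-left corners and between their bottom-right corners, each
normalized by the squared diagonal of the *image* canvas (h² + w²):

    MPDIoU = IoU − d₁²/(h² + w²) − d₂²/(h² + w²),    L = 1 − MPDIoU

Because corner distances are zero only for coincident boxes, the loss keeps a
useful gradient even when boxes are disjoint (where IoU is flat at zero), and
it distinguishes same-aspect-ratio boxes of different absolute size.

Boxes are corner-form (x1, y1, x2, y2) in continuous 0-based pixel
coordinates; areas are (x2−x1)·(y2−y1) with no half-open pixel convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "Box",
    "Canvas",
    "MPDIOUResult",
    "DegenerateBoxError",
    "iou",
    "mpdiou",
    "mpdiou_loss_batch",
    "iou_xyxy",
    "mpdiou_loss_xyxy",
    "mpdiou_loss_tensor",
]

#: minimum side length substituted for degenerate predictions during training
_MIN_SIDE = 1e-6


class DegenerateBoxError(ValueError):
    """A box with non-positive width or height where a valid one is required."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in corner form, x2 > x1 and y2 > y1."""

    x1: float
    y1: float
    x2: float
    y2: float

    def validate(self) -> "Box":
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise DegenerateBoxError(f"degenerate box {self}")
        return self

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)


@dataclass(frozen=True)
class Canvas:
    """Image width and height in pixels; normalizes the corner penalties."""

    w: int
    h: int

    def validate(self) -> "Canvas":
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"canvas must have positive dimensions, got {self}")
        return self

    @property
    def diag_sq(self) -> float:
        return float(self.h) ** 2 + float(self.w) ** 2


@dataclass(frozen=True)
class MPDIOUResult:
    iou: float
    d1_sq: float
    d2_sq: float
    mpdiou: float
    loss: float


# -- vectorized cores ---------------------------------------------------

def iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of corner-form boxes; a and b broadcast over (..., 4)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    x1 = np.maximum(a[..., 0], b[..., 0])
    y1 = np.maximum(a[..., 1], b[..., 1])
    x2 = np.minimum(a[..., 2], b[..., 2])
    y2 = np.minimum(a[..., 3], b[..., 3])
    # two-branch intersection: positive only when the boxes genuinely overlap
    inter = np.where((x2 > x1) & (y2 > y1), (x2 - x1) * (y2 - y1), 0.0)
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    return inter / (area_a + area_b - inter)


def mpdiou_loss_xyxy(pred: np.ndarray, gt: np.ndarray, canvas: Canvas):
    """Vectorized (iou, d1², d2², mpdiou, loss) for (..., 4) box arrays."""
    canvas.validate()
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    i = iou_xyxy(pred, gt)
    d1 = (pred[..., 0] - gt[..., 0]) ** 2 + (pred[..., 1] - gt[..., 1]) ** 2
    d2 = (pred[..., 2] - gt[..., 2]) ** 2 + (pred[..., 3] - gt[..., 3]) ** 2
    mpd = i - d1 / canvas.diag_sq - d2 / canvas.diag_sq
    return i, d1, d2, mpd, 1.0 - mpd


# -- scalar public API --------------------------------------------------

def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two valid boxes."""
    a.validate()
    b.validate()
    return float(iou_xyxy(a.as_array(), b.as_array()))


def mpdiou(pred: Box, gt: Box, canvas: Canvas) -> MPDIOUResult:
    """MPDIoU of a predicted box against a ground-truth box on a canvas."""
    pred.validate()
    gt.validate()
    i, d1, d2, mpd, loss = mpdiou_loss_xyxy(pred.as_array(), gt.as_array(), canvas)
    return MPDIOUResult(float(i), float(d1), float(d2), float(mpd), float(loss))


def mpdiou_loss_batch(preds, gts, canvas: Canvas) -> float:
    """Mean MPDIoU loss over matched (pred, gt) box pairs.

    Empty input contributes 0 (a batch with no positive matches).  Degenerate
    predicted boxes — which arise mid-optimization — are clamped to a minimum
    side of 1e−6 instead of rejected, so training never halts.
    """
    preds = list(preds)
    gts = list(gts)
    if len(preds) != len(gts):
        raise ValueError("preds and gts must have equal length")
    if not preds:
        return 0.0
    p = np.stack([b.as_array() if isinstance(b, Box) else np.asarray(b, float)
                  for b in preds])
    g = np.stack([b.as_array() if isinstance(b, Box) else np.asarray(b, float)
                  for b in gts])
    p = _clamp_degenerate(p)
    return float(np.mean(mpdiou_loss_xyxy(p, g, canvas)[4]))


def _clamp_degenerate(p: np.ndarray) -> np.ndarray:
    p = p.copy()
    p[:, 2] = np.maximum(p[:, 2], p[:, 0] + _MIN_SIDE)
    p[:, 3] = np.maximum(p[:, 3], p[:, 1] + _MIN_SIDE)
    return p


# -- differentiable route (training) ------------------------------------

def mpdiou_loss_tensor(pred: "nn.Tensor", gt: np.ndarray, canvas: Canvas) -> "nn.Tensor":
    """Mean MPDIoU loss on an (N, 4) prediction tensor, differentiable.

    ``gt`` is a constant (N, 4) array of matched ground-truth boxes.  The IoU
    intersection is expressed with clamped widths/heights so the disjoint
    branch (I = 0) and its zero gradient come out of the same expression.
    """
    canvas.validate()
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape[0] == 0:
        return nn.Tensor(0.0)
    px1, py1 = pred[:, 0], pred[:, 1]
    px2 = nn.maximum(pred[:, 2] - pred[:, 0], _MIN_SIDE) + pred[:, 0]
    py2 = nn.maximum(pred[:, 3] - pred[:, 1], _MIN_SIDE) + pred[:, 1]
    gx1, gy1, gx2, gy2 = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]

    def _max(a, b):
        bt = nn.as_tensor(b)
        return nn.relu(a - bt) + bt

    def _min(a, b):
        bt = nn.as_tensor(b)
        return bt - nn.relu(bt - a)

    iw = _min(px2, gx2) - _max(px1, gx1)
    ih = _min(py2, gy2) - _max(py1, gy1)
    inter = nn.relu(iw) * nn.relu(ih)
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    i = inter / (area_p + area_g - inter)
    norm = 1.0 / canvas.diag_sq
    d1 = (px1 - gx1) ** 2.0 + (py1 - gy1) ** 2.0
    d2 = (px2 - gx2) ** 2.0 + (py2 - gy2) ** 2.0
    mpd = i - d1 * norm - d2 * norm
    return (1.0 - mpd).mean()
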