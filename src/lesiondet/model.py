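"""The assembled anchor-free detector: backbone + neck + head.

Every C2f block (backbone and neck) is followed by an LSKA attention block,
and the backbone terminates in SPPF-CA.  The head is anchor-free: at each
feature-map cell of each stride it emits 4 box-regression channels
(tx, ty, tw, th) and one logit per class.  A cell's box decodes as

    cx = (j + σ(tx))·s,   cy = (i + σ(ty))·s,   w = exp(tw)·s,   h = exp(th)·s

on the input canvas (stride s).  Training uses binary cross-entropy on the
class logits plus the MPDIoU loss on boxes decoded at positively assigned
cells; assignment is the simplest center-in-cell rule with one scale per
target chosen by box size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .attention import LSKA
from .blocks import C2f, C2fLSKA, ConvBNAct, SPPFCA
from .boxgeom import Box, Canvas, iou_xyxy, mpdiou_loss_tensor
from .nn import Tensor

__all__ = ["ModelConfig", "Detection", "Detector", "build_model",
           "decode_detections", "training_loss", "save_checkpoint",
           "load_checkpoint"]

_TWH_CLIP = (-8.0, 4.0)  # stability clamp on log-size regression channels


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 64
    width_mult: float = 0.25
    num_classes: int = 4
    strides: tuple = (8, 16)
    lska_k: int = 11
    lska_d: int = 3
    ca_r: int = 4
    cls_weight: float = 1.0
    box_weight: float = 5.0
    conf_thr: float = 0.25
    nms_iou: float = 0.45

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("need at least one class")
        if tuple(self.strides) != (8, 16):
            raise ValueError("this desk-scale layout emits heads at strides (8, 16)")
        if self.input_size % max(self.strides):
            raise ValueError(
                f"input size {self.input_size} not divisible by stride {max(self.strides)}")

    def channels(self) -> tuple:
        """Stage widths: base (64, 128, 256, 256) scaled and rounded to even."""
        def ch(base):
            v = max(8, int(round(base * self.width_mult)))
            return v + (v % 2)
        return ch(64), ch(128), ch(256), ch(256)


@dataclass(frozen=True)
class Detection:
    box: Box
    class_id: int
    confidence: float

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


class Detector(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c1, c2, c3, c4 = cfg.channels()
        k, d, r = cfg.lska_k, cfg.lska_d, cfg.ca_r
        nc = cfg.num_classes
        self.stem1 = ConvBNAct(1, c1, 3, stride=2, rng=rng)
        self.stem2 = ConvBNAct(c1, c2, 3, stride=2, rng=rng)
        self.c2f_s4 = C2fLSKA(c2, c2, k=k, d=d, rng=rng)
        self.down3 = ConvBNAct(c2, c3, 3, stride=2, rng=rng)
        self.c2f_s8 = C2fLSKA(c3, c3, k=k, d=d, rng=rng)
        self.down4 = ConvBNAct(c3, c4, 3, stride=2, rng=rng)
        self.c2f_s16 = C2fLSKA(c4, c4, k=k, d=d, rng=rng)
        self.sppf_ca = SPPFCA(c4, c4, ca_r=r, rng=rng)
        # neck: top-down then bottom-up fusion, one C2f+LSKA per merge
        self.c2f_n3 = C2fLSKA(c4 + c3, c3, k=k, d=d, rng=rng)
        self.down_n = ConvBNAct(c3, c3, 3, stride=2, rng=rng)
        self.c2f_n4 = C2fLSKA(c3 + c4, c4, k=k, d=d, rng=rng)
        self.head3_conv = ConvBNAct(c3, c3, 3, rng=rng)
        self.head3_out = nn.Conv2d(c3, 4 + nc, 1, rng=rng)
        self.head4_conv = ConvBNAct(c4, c4, 3, rng=rng)
        self.head4_out = nn.Conv2d(c4, 4 + nc, 1, rng=rng)
        # rare-positive prior: quiet head init, class logits strongly negative
        for head in (self.head3_out, self.head4_out):
            head.weight.data *= 0.1
            head.bias.data[4:] = -6.0

    def forward(self, x: Tensor) -> list[Tensor]:
        """x: (N, 1, H, W) in [0, 1] → raw head maps at strides 8 and 16."""
        y = self.stem2(self.stem1(x))
        y = self.c2f_s4(y)
        p3 = self.c2f_s8(self.down3(y))
        p4 = self.c2f_s16(self.down4(p3))
        p4 = self.sppf_ca(p4)
        n3 = self.c2f_n3(nn.concat([nn.upsample2x(p4), p3], axis=1))
        n4 = self.c2f_n4(nn.concat([self.down_n(n3), p4], axis=1))
        out3 = self.head3_out(self.head3_conv(n3))
        out4 = self.head4_out(self.head4_conv(n4))
        return [out3, out4]

    def predict_raw(self, images: np.ndarray) -> list[np.ndarray]:
        """Forward pass without gradient tracking; images (N, H, W) in [0, 1]."""
        self.eval()
        outs = self.forward(Tensor(np.asarray(images, dtype=np.float64)[:, None]))
        return [o.data for o in outs]


def build_model(cfg: ModelConfig, seed: int = 0) -> Detector:
    return Detector(cfg, rng=np.random.default_rng(seed))


# -- decode --------------------------------------------------------------

def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-np.clip(v, -60, 60)))


def _decode_scale(raw: np.ndarray, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """raw (N, 4+nc, H, W) → boxes (N, H*W, 4) xyxy and scores (N, H*W, nc)."""
    n, _, h, w = raw.shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    cx = (jj + _sigmoid(raw[:, 0])) * stride
    cy = (ii + _sigmoid(raw[:, 1])) * stride
    bw = np.exp(np.clip(raw[:, 2], *_TWH_CLIP)) * stride
    bh = np.exp(np.clip(raw[:, 3], *_TWH_CLIP)) * stride
    boxes = np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=-1)
    scores = _sigmoid(raw[:, 4:])
    return boxes.reshape(n, h * w, 4), scores.transpose(0, 2, 3, 1).reshape(n, h * w, -1)


def decode_detections(raws: list[np.ndarray], cfg: ModelConfig,
                      conf_thr: float | None = None,
                      nms_iou: float | None = None,
                      max_det: int = 100) -> list[list[Detection]]:
    """Raw head outputs → thresholded, class-wise-NMS-filtered detections."""
    conf_thr = cfg.conf_thr if conf_thr is None else conf_thr
    nms_iou = cfg.nms_iou if nms_iou is None else nms_iou
    for name, v in (("confidence threshold", conf_thr), ("NMS IoU threshold", nms_iou)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    n = raws[0].shape[0]
    all_boxes, all_scores = [], []
    for raw, s in zip(raws, cfg.strides):
        b, sc = _decode_scale(raw, s)
        all_boxes.append(b)
        all_scores.append(sc)
    boxes = np.concatenate(all_boxes, axis=1)
    scores = np.concatenate(all_scores, axis=1)
    results = []
    for img in range(n):
        results.append(_nms_image(boxes[img], scores[img], conf_thr, nms_iou, max_det))
    return results


def _nms_image(boxes, scores, conf_thr, nms_iou, max_det) -> list[Detection]:
    cand_cell, cand_cls = np.nonzero(scores >= conf_thr)
    if cand_cell.size == 0:
        return []
    conf = scores[cand_cell, cand_cls]
    order = np.argsort(-conf, kind="stable")
    kept: list[Detection] = []
    kept_boxes, kept_cls = [], []
    for idx in order:
        if len(kept) >= max_det:
            break
        b = boxes[cand_cell[idx]]
        c = int(cand_cls[idx])
        if b[2] <= b[0] or b[3] <= b[1]:
            continue
        suppressed = False
        for kb, kc in zip(kept_boxes, kept_cls):
            if kc == c and float(iou_xyxy(b, kb)) > nms_iou:
                suppressed = True
                break
        if suppressed:
            continue
        kept.append(Detection(Box(*map(float, b)), c, float(conf[idx])))
        kept_boxes.append(b)
        kept_cls.append(c)
    return kept


# -- training loss -------------------------------------------------------

def assign_targets(targets: list, cfg: ModelConfig):
    """Center-in-cell assignment, one positive cell per target.

    ``targets`` is a per-image list of (boxes (M, 4) xyxy, classes (M,)).
    A target goes to the stride-8 head when max(w, h) ≤ 4·8 px, otherwise to
    the stride-16 head.  Returns per-scale index arrays and a one-hot class
    target map per scale.
    """
    sz = cfg.input_size
    shapes = [(sz // s, sz // s) for s in cfg.strides]
    pos = [{"img": [], "i": [], "j": [], "cls": [], "box": []} for _ in cfg.strides]
    for img, (boxes, classes) in enumerate(targets):
        for b, c in zip(np.asarray(boxes, float).reshape(-1, 4), classes):
            size = max(b[2] - b[0], b[3] - b[1])
            k = 0 if size <= 4 * cfg.strides[0] else 1
            s = cfg.strides[k]
            h, w = shapes[k]
            j = int(np.clip((b[0] + b[2]) / 2 / s, 0, w - 1))
            i = int(np.clip((b[1] + b[3]) / 2 / s, 0, h - 1))
            p = pos[k]
            p["img"].append(img)
            p["i"].append(i)
            p["j"].append(j)
            p["cls"].append(int(c))
            p["box"].append(b)
    return pos, shapes


def training_loss(raws: list[Tensor], targets: list, cfg: ModelConfig):
    """Classification BCE + weighted mean MPDIoU loss on assigned cells.

    Returns (total: Tensor, parts: dict of floats).  With no positive matches
    the box term contributes 0.
    """
    n = raws[0].shape[0]
    pos, shapes = assign_targets(targets, cfg)
    num_pos = sum(len(p["img"]) for p in pos)
    canvas = Canvas(cfg.input_size, cfg.input_size)
    cls_terms, box_terms = [], []
    for k, raw in enumerate(raws):
        h, w = shapes[k]
        t = np.zeros((n, cfg.num_classes, h, w))
        p = pos[k]
        if p["img"]:
            t[p["img"], p["cls"], p["i"], p["j"]] = 1.0
        cls_terms.append(nn.bce_with_logits(raw[:, 4:, :, :], t).sum())
        if p["img"]:
            s = cfg.strides[k]
            ii = np.array(p["i"])
            jj = np.array(p["j"])
            im = np.array(p["img"])
            tx = raw[im, np.zeros_like(im), ii, jj]
            ty = raw[im, np.ones_like(im), ii, jj]
            tw = raw[im, np.full_like(im, 2), ii, jj]
            th = raw[im, np.full_like(im, 3), ii, jj]
            cx = (nn.sigmoid(tx) + jj) * float(s)
            cy = (nn.sigmoid(ty) + ii) * float(s)
            bw = nn.exp(nn.clip(tw, *_TWH_CLIP)) * float(s)
            bh = nn.exp(nn.clip(th, *_TWH_CLIP)) * float(s)
            m = len(p["img"])
            pred = nn.concat([(cx - bw * 0.5).reshape(m, 1),
                              (cy - bh * 0.5).reshape(m, 1),
                              (cx + bw * 0.5).reshape(m, 1),
                              (cy + bh * 0.5).reshape(m, 1)], axis=1)
            gt = np.stack(p["box"])
            box_terms.append((mpdiou_loss_tensor(pred, gt, canvas), m))
    denom = float(max(1, num_pos))
    cls_loss = (cls_terms[0] + cls_terms[1]) * (1.0 / denom)
    if box_terms:
        box_loss = box_terms[0][0] * (box_terms[0][1] / denom)
        for t, m in box_terms[1:]:
            box_loss = box_loss + t * (m / denom)
    else:
        box_loss = nn.Tensor(0.0)
    total = cls_loss * cfg.cls_weight + box_loss * cfg.box_weight
    parts = {"cls": float(cls_loss.data) * cfg.cls_weight,
             "box": float(box_loss.data) * cfg.box_weight,
             "total": float(total.data),
             "num_pos": num_pos}
    return total, parts


# -- checkpointing -------------------------------------------------------

def save_checkpoint(path, model: Detector) -> None:
    """Self-describing .npz: model config JSON + every weight array."""
    state = model.state_dict()
    meta = json.dumps(asdict(model.cfg))
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{k: v for k, v in state.items()})


def load_checkpoint(path) -> Detector:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__config__"]).decode())
        meta["strides"] = tuple(meta["strides"])
        cfg = ModelConfig(**meta)
        model = build_model(cfg)
        model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    return model
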