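"""Training and evaluation driver: single-split training and k-fold CV.

The loop follows the usual fold/epoch/step nesting: for every fold, train
with the classification + MPDIoU loss, keep the weights of the epoch with
the best validation mAP50, evaluate that model on the fold's validation
split, and finally aggregate mean ± sd of every metric across folds.

Optimization defaults to Adam with linear warmup and cosine decay (momentum
SGD is available via ``RunConfig.optimizer``).  The optimizer family and
schedule are desk-scale defaults, configurable and not load-bearing for any
reported quantity.  All randomness (weight init, batch shuffling, data
generation, augmentation) derives from the single run seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import EvalReport, GroundTruth, aggregate_reports, evaluate_detections, map50
from .model import (Detector, ModelConfig, build_model, decode_detections,
                    load_checkpoint, save_checkpoint, training_loss)
from .nn import SGD, Tensor
from .nn.layers import Adam
from .syndata import (CaseRegistry, augment_samples, generate_study,
                      kfold_partitions, full_registry, tiny_registry)

__all__ = ["RunConfig", "FoldResult", "prepare_study", "train_once", "run_cv",
           "evaluate"]


@dataclass(frozen=True)
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    profile: str = "tiny"            # registry profile: "tiny" or "full"
    epochs: int = 20
    batch_size: int = 8
    optimizer: str = "adam"          # "adam" or "sgd"
    lr: float = 0.003
    momentum: float = 0.9
    weight_decay: float = 1e-4
    warmup_epochs: int = 2
    k: int = 5
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("need at least one epoch")

    def registry(self) -> CaseRegistry:
        if self.profile == "tiny":
            return tiny_registry()
        if self.profile == "full":
            return full_registry()
        raise ValueError(f"unknown profile {self.profile!r}")


@dataclass
class FoldResult:
    fold: int
    trace: pd.DataFrame                  # per-epoch cls/box/total loss + val mAP50
    report: EvalReport                   # best-model evaluation on the val split
    best_epoch: int
    best_map50: float
    checkpoint_path: str | None = None
    state: dict | None = None            # best weights (in memory)


def prepare_study(registry: CaseRegistry, image_size: int, seed: int):
    """Generate originals and apply per-subtype minority augmentation."""
    samples = generate_study(registry, image_size=image_size, seed=seed)
    out = []
    for class_id, spec in registry.subtypes:
        cls_samples = [s for s in samples if s.class_id == class_id]
        out.extend(augment_samples(cls_samples, spec.augment_factor,
                                   seed=seed * 7 + class_id + 1))
    return out


def _as_targets(samples):
    targets = []
    for s in samples:
        boxes = np.array([b.as_array() for b in s.boxes]).reshape(-1, 4)
        targets.append((boxes, [s.class_id] * len(s.boxes)))
    return targets


def _lr_at(cfg: RunConfig, epoch: int) -> float:
    if epoch < cfg.warmup_epochs:
        return cfg.lr * (epoch + 1) / (cfg.warmup_epochs + 1)
    span = max(1, cfg.epochs - cfg.warmup_epochs)
    prog = (epoch - cfg.warmup_epochs) / span
    return cfg.lr * (0.05 + 0.95 * 0.5 * (1.0 + math.cos(math.pi * prog)))


def _detect_split(model: Detector, samples, batch: int = 16, conf=None, nms=None):
    dets = []
    for lo in range(0, len(samples), batch):
        chunk = samples[lo:lo + batch]
        raws = model.predict_raw(np.stack([s.image for s in chunk]) / 255.0)
        dets.extend(decode_detections(raws, model.cfg, conf_thr=conf, nms_iou=nms))
    return dets


def _gts(samples):
    return [[GroundTruth(b, s.class_id) for b in s.boxes] for s in samples]


def train_once(cfg: RunConfig, train_samples, val_samples, fold: int = 0,
               verbose: bool = False) -> FoldResult:
    """Train on one split; checkpoint the epoch with the best validation mAP50."""
    model = build_model(cfg.model, seed=cfg.seed * 1000 + fold)
    if cfg.optimizer == "adam":
        opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    elif cfg.optimizer == "sgd":
        opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                  weight_decay=cfg.weight_decay)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    rng = np.random.default_rng([cfg.seed, fold, 17])
    x = np.stack([s.image for s in train_samples]).astype(np.float64) / 255.0
    targets = _as_targets(train_samples)
    n = len(train_samples)
    rows = []
    best_map, best_epoch, best_state = -1.0, -1, None
    for epoch in range(cfg.epochs):
        opt.lr = _lr_at(cfg, epoch)
        order = rng.permutation(n)
        model.train()
        ep = {"cls": 0.0, "box": 0.0, "total": 0.0}
        nb = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            raws = model.forward(Tensor(x[idx][:, None]))
            total, parts = training_loss(raws, [targets[i] for i in idx], cfg.model)
            if not math.isfinite(parts["total"]):
                raise RuntimeError(
                    f"non-finite loss in fold {fold}, epoch {epoch}, "
                    f"batch starting at sample {lo}")
            opt.zero_grad()
            total.backward()
            opt.step()
            for key in ep:
                ep[key] += parts[key]
            nb += 1
        val_dets = _detect_split(model, val_samples)
        val_map = map50(val_dets, _gts(val_samples))
        rows.append({"epoch": epoch, "lr": opt.lr, "cls": ep["cls"] / nb,
                     "box": ep["box"] / nb, "total": ep["total"] / nb,
                     "val_map50": val_map})
        if val_map > best_map:
            best_map, best_epoch = val_map, epoch
            best_state = model.state_dict()
        if verbose:
            print(f"fold {fold} epoch {epoch:3d} loss {ep['total']/nb:7.4f} "
                  f"(cls {ep['cls']/nb:6.4f} box {ep['box']/nb:6.4f}) "
                  f"val mAP50 {val_map:.3f}")
    model.load_state_dict(best_state)
    report = evaluate(model, val_samples)
    path = None
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = str(out / f"fold{fold}_best.npz")
        save_checkpoint(path, model)
        pd.DataFrame(rows).to_csv(out / f"fold{fold}_trace.csv", index=False)
    return FoldResult(fold=fold, trace=pd.DataFrame(rows), report=report,
                      best_epoch=best_epoch, best_map50=best_map,
                      checkpoint_path=path, state=best_state)


def evaluate(model_or_checkpoint, samples) -> EvalReport:
    """Deterministic evaluation of a model (or checkpoint path) on a split."""
    if not samples:
        raise ValueError("nothing to evaluate: empty split")
    model = (model_or_checkpoint if isinstance(model_or_checkpoint, Detector)
             else load_checkpoint(model_or_checkpoint))
    classes = {s.class_id for s in samples}
    if max(classes) >= model.cfg.num_classes:
        raise ValueError("split contains class ids beyond the model's class count")
    dets = _detect_split(model, samples)
    return evaluate_detections(dets, _gts(samples), model.cfg.num_classes)


def run_cv(cfg: RunConfig, samples=None, verbose: bool = False):
    """K-fold cross-validation; returns (fold results, aggregate table)."""
    if samples is None:
        samples = prepare_study(cfg.registry(), cfg.model.input_size, cfg.seed)
    folds = kfold_partitions(samples, cfg.k, seed=cfg.seed)
    results = []
    for f, (train_split, val_split) in enumerate(folds):
        results.append(train_once(cfg, train_split, val_split, fold=f,
                                  verbose=verbose))
    table = aggregate_reports([r.report for r in results])
    table.attrs["map50_mean"] = float(np.mean([r.report.map50 for r in results]))
    table.attrs["map50_sd"] = float(np.std([r.report.map50 for r in results], ddof=1))
    if cfg.out_dir is not None:
        table.to_csv(Path(cfg.out_dir) / "cv_report.csv")
    return results, table
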