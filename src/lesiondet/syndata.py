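"""Synthetic CT-slice study generator and data preparation.

The generator emulates the shape of a four-subtype lung-cancer CT study:
grayscale 2-D slices with one lesion each, subtype-conditional lesion
appearance, and a case registry with per-subtype case counts, slices per
case and minority-class augmentation.  Class ids follow the study coding:

    0 — small cell carcinoma (SCLC): small bright round blob
    1 — large cell carcinoma (LCC): large round blob
    2 — adenocarcinoma (ADC): diffuse low-contrast textured patch
    3 — squamous cell carcinoma (SCC): irregular mass near the lung center

The default (full study) registry is 429 ADC / 44 SCLC / 119 LCC /
243 SCC cases with 3/10/10/5 slices per case, giving 1287/440/1190/1215
original images, and the SCLC minority class is doubled to 880 by
rotation/translation augmentation.  A reduced "tiny" profile (~200 images)
with the same structure serves desk-scale training runs.

Everything is deterministic given the seed; labels round-trip through the
normalized ``class cx cy w h`` text dialect alongside PNG images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

from .boxgeom import Box

__all__ = [
    "SCLC", "LCC", "ADC", "SCC", "CLASS_NAMES",
    "SubtypeSpec", "CaseRegistry", "SliceSample", "AugmentParams",
    "full_registry", "tiny_registry", "select_slices",
    "generate_study", "rotate_point", "translate_point", "augment_samples",
    "split_dataset", "kfold_partitions", "write_dataset", "read_dataset",
    "box_to_yolo_row", "yolo_row_to_box",
]

SCLC, LCC, ADC, SCC = 0, 1, 2, 3
CLASS_NAMES = {SCLC: "SCLC", LCC: "LCC", ADC: "ADC", SCC: "SCC"}


@dataclass(frozen=True)
class SubtypeSpec:
    cases: int
    slices_per_case: int
    augment_factor: int = 1

    def __post_init__(self):
        if self.cases < 0 or self.slices_per_case < 0 or self.augment_factor < 1:
            raise ValueError(f"invalid subtype spec {self}")


@dataclass(frozen=True)
class CaseRegistry:
    subtypes: tuple  # of (class_id, SubtypeSpec), ordered by class id

    @classmethod
    def from_dict(cls, d: dict) -> "CaseRegistry":
        return cls(tuple(sorted((int(k), v if isinstance(v, SubtypeSpec)
                                 else SubtypeSpec(**v)) for k, v in d.items())))

    def spec(self, class_id: int) -> SubtypeSpec:
        return dict(self.subtypes)[class_id]

    def expected_counts(self) -> dict:
        """Original (pre-augmentation) image count per class."""
        return {c: s.cases * s.slices_per_case for c, s in self.subtypes}

    def to_yaml(self, path) -> None:
        d = {int(c): {"cases": s.cases, "slices_per_case": s.slices_per_case,
                      "augment_factor": s.augment_factor} for c, s in self.subtypes}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "CaseRegistry":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def full_registry() -> CaseRegistry:
    """The full study profile: case counts, slice counts, SCLC doubling."""
    return CaseRegistry.from_dict({
        SCLC: SubtypeSpec(44, 10, augment_factor=2),
        LCC: SubtypeSpec(119, 10),
        ADC: SubtypeSpec(429, 3),
        SCC: SubtypeSpec(243, 5),
    })


def tiny_registry() -> CaseRegistry:
    """Reduced desk-scale profile (~200 images) with the same structure."""
    return CaseRegistry.from_dict({
        SCLC: SubtypeSpec(6, 5, augment_factor=2),
        LCC: SubtypeSpec(8, 5),
        ADC: SubtypeSpec(17, 3),
        SCC: SubtypeSpec(10, 5),
    })


@dataclass
class SliceSample:
    case_id: str
    class_id: int
    image: np.ndarray          # (H, W) uint8 grayscale
    boxes: list                # list of Box on the image canvas
    provenance: str = "original"

    def canvas_size(self) -> tuple:
        return self.image.shape[1], self.image.shape[0]


@dataclass(frozen=True)
class AugmentParams:
    cx: float
    cy: float
    theta: float   # radians in [0, 2π)
    dx: float
    dy: float


def select_slices(available: int, n: int) -> list[int]:
    """Slice-selection rule within a case: the first n slice indices.

    Which slices the original study took from each volume is not recoverable;
    the first-n rule keeps the counts bookkeeping testable on its own.
    """
    if n > available:
        raise ValueError(f"cannot select {n} slices from {available}")
    return list(range(n))


# -- image synthesis -----------------------------------------------------

def _background(rng: np.random.Generator, size: int) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    low = ndimage.gaussian_filter(noise, sigma=size / 8.0)
    low = (low - low.min()) / max(float(np.ptp(low)), 1e-9)
    return 0.08 + 0.22 * low


def _lesion(rng: np.random.Generator, size: int, class_id: int):
    """Lesion intensity field and its tight bounding box."""
    margin = size // 5
    if class_id == SCLC:
        r = rng.uniform(0.04, 0.08) * size
        amp, power, texture = 0.9, 4.0, 0.0
    elif class_id == LCC:
        r = rng.uniform(0.14, 0.22) * size
        amp, power, texture = 0.8, 4.0, 0.0
    elif class_id == ADC:
        r = rng.uniform(0.09, 0.16) * size
        amp, power, texture = 0.45, 2.0, 0.5
    elif class_id == SCC:
        r = rng.uniform(0.11, 0.18) * size
        amp, power, texture = 0.85, 4.0, 0.0
    else:
        raise ValueError(f"unknown class id {class_id}")
    if size < 2 * (margin + 2) or r < 1.0:
        raise ValueError(f"image size {size} too small to place a lesion")
    if class_id == SCC:
        # central irregular mass
        cx = size / 2 + rng.uniform(-size / 8, size / 8)
        cy = size / 2 + rng.uniform(-size / 8, size / 8)
    else:
        cx = rng.uniform(margin, size - margin)
        cy = rng.uniform(margin, size - margin)
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    dist = np.hypot(dx, dy)
    if class_id == SCC:
        ang = np.arctan2(dy, dx)
        wobble = 1.0
        for h in (2, 3, 5):
            wobble = wobble + rng.uniform(0.05, 0.18) * np.cos(h * ang + rng.uniform(0, 2 * math.pi))
        r_eff = r * wobble
    else:
        r_eff = r
    field = amp * np.exp(-((dist / np.maximum(r_eff, 1e-6)) ** power))
    if texture > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=1.5)
        tex = 1.0 + texture * (tex / max(np.abs(tex).max(), 1e-9))
        field = field * tex
    support = field > 0.3 * amp
    if not support.any():
        raise ValueError("lesion support empty; image too small")
    ys, xs = np.nonzero(support)
    box = Box(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))
    return field, box


def generate_study(registry: CaseRegistry, image_size: int = 64,
                   seed: int = 0) -> list[SliceSample]:
    """All original slice samples of a study, reproducible from the seed."""
    if image_size < 24:
        raise ValueError(f"image size {image_size} too small to place a lesion")
    samples = []
    for class_id, spec in registry.subtypes:
        for case in range(spec.cases):
            case_id = f"{CLASS_NAMES[class_id]}_{case:04d}"
            for slc in select_slices(spec.slices_per_case, spec.slices_per_case):
                rng = np.random.default_rng([seed, class_id, case, slc])
                img = _background(rng, image_size)
                lesion, box = _lesion(rng, image_size, class_id)
                img = np.clip(img + lesion, 0.0, 1.0)
                samples.append(SliceSample(
                    case_id=case_id, class_id=class_id,
                    image=np.round(img * 255).astype(np.uint8),
                    boxes=[box], provenance="original"))
    return samples


# -- geometric transforms ------------------------------------------------

def rotate_point(p, center, theta: float):
    """Rotate (x, y) about (cx, cy) by theta radians (counterclockwise)."""
    x, y = p
    cx, cy = center
    ct, st = math.cos(theta), math.sin(theta)
    return ((x - cx) * ct - (y - cy) * st + cx,
            (x - cx) * st + (y - cy) * ct + cy)


def translate_point(p, offset):
    x, y = p
    dx, dy = offset
    return (x + dx, y + dy)


def _warp_image(image: np.ndarray, params: AugmentParams) -> np.ndarray:
    """Apply rotation about (cx, cy) then translation, bilinear resampling."""
    ct, st = math.cos(params.theta), math.sin(params.theta)
    # inverse map in (row, col) = (y, x) ordering for scipy
    minv = np.array([[ct, st], [-st, ct]])
    center_out = np.array([params.cy + params.dy, params.cx + params.dx])
    center_in = np.array([params.cy, params.cx])
    offset = center_in - minv @ center_out
    warped = ndimage.affine_transform(image.astype(np.float64), minv, offset=offset,
                                      order=1, mode="constant", cval=float(image.min()))
    return np.clip(np.round(warped), 0, 255).astype(np.uint8)


def _transform_box(box: Box, params: AugmentParams, size_wh) -> Box | None:
    """Axis-aligned envelope of the rotated corners, then canvas clip."""
    corners = [(box.x1, box.y1), (box.x2, box.y1), (box.x1, box.y2), (box.x2, box.y2)]
    pts = [translate_point(rotate_point(p, (params.cx, params.cy), params.theta),
                           (params.dx, params.dy)) for p in corners]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    w, h = size_wh
    x1, y1 = max(0.0, min(xs)), max(0.0, min(ys))
    x2, y2 = min(float(w), max(xs)), min(float(h), max(ys))
    if x2 - x1 < 1.0 or y2 - y1 < 1.0:
        return None
    return Box(x1, y1, x2, y2)


def _default_param_sampler(rng: np.random.Generator, sample: SliceSample) -> AugmentParams:
    """±15° rotation about the image center, ±10 % of canvas translation."""
    w, h = sample.canvas_size()
    theta = math.radians(rng.uniform(-15.0, 15.0)) % (2 * math.pi)
    return AugmentParams(cx=w / 2.0, cy=h / 2.0, theta=theta,
                         dx=rng.uniform(-0.1, 0.1) * w, dy=rng.uniform(-0.1, 0.1) * h)


def augment_samples(samples, factor: int, param_sampler=None, seed: int = 0,
                    max_retries: int = 20):
    """Grow a sample list to ``len(samples) × factor`` by rotation/translation.

    The originals are kept; each contributes ``factor − 1`` augmented copies.
    A draw whose boxes all leave the canvas is redrawn (bounded retries).
    """
    if factor < 1:
        raise ValueError("augmentation factor must be >= 1")
    samples = list(samples)
    if factor == 1:
        return samples
    sampler = param_sampler or _default_param_sampler
    out = list(samples)
    for idx, sample in enumerate(samples):
        for rep in range(factor - 1):
            rng = np.random.default_rng([seed, idx, rep])
            for attempt in range(max_retries):
                params = sampler(rng, sample)
                new_boxes = [_transform_box(b, params, sample.canvas_size())
                             for b in sample.boxes]
                if sample.boxes and all(b is None for b in new_boxes):
                    continue
                new_boxes = [b for b in new_boxes if b is not None]
                out.append(replace(sample, image=_warp_image(sample.image, params),
                                   boxes=new_boxes, provenance="augmented"))
                break
            else:
                raise RuntimeError(
                    f"augmentation of sample {idx} kept no box after {max_retries} draws")
    return out


# -- splits --------------------------------------------------------------

def _cases_by_class(samples):
    groups: dict = {}
    for s in samples:
        groups.setdefault(s.class_id, {}).setdefault(s.case_id, []).append(s)
    return groups


def split_dataset(samples, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Case-level stratified train/val/test split, nearest-case proportions."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    groups = _cases_by_class(samples)
    total_cases = sum(len(v) for v in groups.values())
    if total_cases < len(ratios):
        raise ValueError("fewer cases than partitions")
    rng = np.random.default_rng(seed)
    parts = ([], [], [])
    for class_id in sorted(groups):
        cases = sorted(groups[class_id])
        rng.shuffle(cases)
        n = len(cases)
        n_val = int(round(ratios[1] * n))
        n_test = int(round(ratios[2] * n))
        n_train = n - n_val - n_test
        bounds = [0, n_train, n_train + n_val, n]
        for p in range(3):
            for cid in cases[bounds[p]:bounds[p + 1]]:
                parts[p].extend(groups[class_id][cid])
    return parts


def kfold_partitions(samples, k: int, seed: int = 0):
    """Case-level stratified k-fold: each case validates in exactly one fold."""
    if k < 2:
        raise ValueError("need k >= 2 folds")
    groups = _cases_by_class(samples)
    total_cases = sum(len(v) for v in groups.values())
    if k > total_cases:
        raise ValueError(f"k={k} exceeds case count {total_cases}")
    rng = np.random.default_rng(seed)
    fold_of_case: dict = {}
    for class_id in sorted(groups):
        cases = sorted(groups[class_id])
        rng.shuffle(cases)
        for pos, cid in enumerate(cases):
            fold_of_case[(class_id, cid)] = pos % k
    folds = []
    for f in range(k):
        train, val = [], []
        for class_id, by_case in groups.items():
            for cid, ss in by_case.items():
                (val if fold_of_case[(class_id, cid)] == f else train).extend(ss)
        folds.append((train, val))
    return folds


# -- YOLO-txt round trip -------------------------------------------------

def box_to_yolo_row(class_id: int, box: Box, size_wh) -> str:
    w, h = size_wh
    cx = (box.x1 + box.x2) / 2.0 / w
    cy = (box.y1 + box.y2) / 2.0 / h
    bw = (box.x2 - box.x1) / w
    bh = (box.y2 - box.y1) / h
    return f"{class_id} {cx:.6g} {cy:.6g} {bw:.6g} {bh:.6g}"


def yolo_row_to_box(row: str, size_wh):
    parts = row.split()
    if len(parts) != 5:
        raise ValueError(f"expected 5 fields, got {len(parts)}")
    cls = int(parts[0])
    cx, cy, bw, bh = (float(v) for v in parts[1:])
    w, h = size_wh
    return cls, Box((cx - bw / 2) * w, (cy - bh / 2) * h,
                    (cx + bw / 2) * w, (cy + bh / 2) * h)


def write_dataset(samples, directory) -> None:
    """Write ``images/*.png`` and ``labels/*.txt`` (one row per box)."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "labels").mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        stem = f"{i:05d}_cls{s.class_id}_{s.case_id}_{s.provenance}"
        Image.fromarray(s.image, mode="L").save(directory / "images" / f"{stem}.png")
        rows = [box_to_yolo_row(s.class_id, b, s.canvas_size()) for b in s.boxes]
        (directory / "labels" / f"{stem}.txt").write_text("\n".join(rows) + ("\n" if rows else ""))


def read_dataset(directory) -> list:
    """Read a directory written by :func:`write_dataset`."""
    directory = Path(directory)
    samples = []
    for img_path in sorted((directory / "images").glob("*.png")):
        stem = img_path.stem
        image = np.asarray(Image.open(img_path).convert("L"))
        parts = stem.split("_")
        class_id = int(parts[1][3:])
        provenance = parts[-1]
        case_id = "_".join(parts[2:-1])
        label_path = directory / "labels" / f"{stem}.txt"
        boxes = []
        if label_path.exists():
            for ln, row in enumerate(label_path.read_text().splitlines(), start=1):
                if not row.strip():
                    continue
                try:
                    cls, box = yolo_row_to_box(row, (image.shape[1], image.shape[0]))
                except ValueError as e:
                    raise ValueError(f"{label_path}:{ln}: malformed label row: {e}") from e
                boxes.append(box)
        samples.append(SliceSample(case_id=case_id, class_id=class_id, image=image,
                                   boxes=boxes, provenance=provenance))
    return samples
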