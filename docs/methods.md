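# Methods

## Problem and model

The package detects and classifies lung-cancer lesions on 2-D CT slices as
an object-detection task: one axis-aligned box plus a subtype label per
lesion, with four subtypes coded 0–3 (small cell carcinoma, large cell
carcinoma, adenocarcinoma, squamous cell carcinoma). The detector is a small
anchor-free single-stage network: a convolutional backbone whose C2f blocks
are each followed by large separable kernel attention (LSKA), an SPPF-CA
pyramid at the backbone exit, a two-scale feature-fusion neck (also C2f +
LSKA), and a per-cell head that emits 4 box-regression channels and one
logit per class at strides 8 and 16.

### Box loss

Box regression minimizes L = 1 − MPDIoU with

MPDIoU = IoU − d₁²/(h²+w²) − d₂²/(h²+w²),

where d₁², d₂² are squared distances between corresponding top-left and
bottom-right corners and (w, h) are the dimensions of the *input image*, not
of either box — the corner penalties are scale-normalized by the canvas
diagonal. Properties relied on by the tests: MPDIoU ≤ IoU with equality
exactly when both corner pairs coincide; the loss is 0 only for an exact
match; disjoint boxes retain a nonzero pull toward the target. Boxes are
corner-form (x1, y1, x2, y2) in continuous 0-based pixel coordinates with
areas (x2−x1)(y2−y1); no half-open pixel convention is applied. Degenerate
predictions arising mid-optimization are clamped to a minimum side of 1e−6
inside the batch loss; the public scalar `mpdiou` operation rejects them
instead.

### LSKA

A k×k depthwise attention kernel (defaults k = 11, d = 3; the receptive
field stays large relative to the 8×8 and 4×4 feature maps used here) is
factored into four 1-D depthwise stages — horizontal and vertical local
kernels of length 2d−1, then horizontal and vertical kernels of length
⌊k/d⌋ with dilation d — followed by a 1×1 mixing convolution; the resulting
map multiplies the input elementwise. ⌊k/d⌋ must be odd so 'same' padding
exists; the configuration is rejected otherwise. The printed formulas for
the decomposition are internally inconsistent about the 1-D lengths (a
(2d+1) and a ⌊d/k⌋ appear once each); the symmetric reading used here —
both local kernels 2d−1, both dilated kernels ⌊k/d⌋ — is the only one that
reproduces the full 2-D LKA operator, which is implemented independently
(`lka_forward`) and used solely as a brute-force oracle: when every 2-D
kernel is the outer product of its 1-D pair, the two routes agree to <1e−5.
The 1×1 mixing convolution is applied before the elementwise product
(conv → product); no alternative ordering is exposed.

### Coordinate attention and SPPF-CA

Coordinate attention pools each channel along width (a per-row profile) and
along height (a per-column profile), concatenates the two profiles, reduces
to C/r channels via a shared 1×1 convolution with batch normalization and a
nonlinearity δ, then maps back per direction and applies sigmoids to obtain
gates g_h(i), g_w(j); the output is x_c(i,j)·g_h(i)·g_w(j). δ is
configurable (`hardswish` default, `sigmoid` optional) since only "a
non-linear activation" is specified. r defaults to 4; r > C is rejected.

SPPF-CA replaces the three serial 5×5 max-pools of classic SPPF with three
separable depthwise stages (1×5 then 5×1, stride 1, 'same' padding,
mirroring the 5×5 pooling footprint). Stage i computes
f_i = DW(f_{i−1}) and contributes f_i gated by the coordinate-attention
gates computed from f_{i−1} (a forward-referencing stage index in the
printed recurrence is not computable in one pass; gating with the preceding
stage follows the prose). The gate reading — multiplying f_i by g_h·g_w
rather than by the full CA output — is forced by the block's reduction
property: with unit gates and identity kernels the block must reduce to the
exit 1×1 of four copies of the entry features, which the full-CA-output
reading violates (it would square the features). CA weights are unshared
across stages. The exit 1×1 consumes entry + 3 gated stages = 4 feature
sets.

### Detector assembly and training loss

Stage widths are (64, 128, 256, 256) scaled by a width multiplier (default
0.25, minimum 8, rounded even) — the desk-scale default is a 64×64 input
with heads at strides 8 and 16; the full-resolution configuration is
reachable through `ModelConfig` but not exercised by any test. All
backbone/neck convolutions are Conv→BatchNorm→SiLU units; without
normalization the multiplicative attention stages make desk-scale training
diverge. The head stays un-normalized, with its final convolution scaled by
0.1 and class biases initialized to −6 (a rare-positive prior that removes
the large initial background loss).

A cell (i, j) at stride s decodes to
cx = (j+σ(tx))·s, cy = (i+σ(ty))·s, w = e^tw·s, h = e^th·s (tw, th clamped
to [−8, 4] for stability). Target assignment is the simplest center-in-cell
rule: each ground-truth box becomes one positive cell on a single scale —
stride 8 when max(w, h) ≤ 32 px, stride 16 otherwise. Classification is
per-class binary cross-entropy over all cells, summed and divided by the
positive count; the box term is the mean MPDIoU loss over positive cells,
weighted 5:1 against classification (total = cls + 5·box). With no
positives in a batch the box term is 0. Inference applies per-class
confidence thresholding (default 0.25) and class-wise greedy NMS (IoU 0.45,
using the same IoU routine as the loss).

Batch normalization falls back to per-instance statistics when the batch
has a single sample (desk-scale batches are tiny); evaluation always uses
running averages.

## Metrics

Box-level matching is greedy in descending confidence: a detection claims
the highest-IoU unmatched same-class ground truth with IoU ≥ threshold.
With distinct confidences this is deterministic and order-independent. AP
is the all-point-interpolated area under the PR curve (monotone precision
envelope; not the 11-point approximation), verified exactly against
enumeration of every confidence cutoff on instances of ≤ 10 detections. mAP
is the unweighted class mean; mAP50–95 averages IoU thresholds
0.50:0.05:0.95 (10 values — the definition text is followed where a table
header says 50–90). True negatives do not exist at box level, so accuracy
and specificity are computed at image level: per (image, class),
predicted-present vs truly-present fills the 2×2 table. The ALL-LESIONS row
is the class-agnostic evaluation with labels collapsed to one class.
Zero-denominator ratios report 0 with a warning. Cross-validation reports
mean ± sd (ddof = 1) of every metric across folds.

## Synthetic data

The generator emulates the *shape* of the source study, not CT physics:
a smoothed low-frequency background in [0.08, 0.30] plus one
subtype-conditional lesion per slice — SCLC: small bright round blob
(radius 4–8 % of the canvas); LCC: large round blob (14–22 %); ADC: diffuse
low-contrast textured patch (9–16 %, amplitude 0.45 with multiplicative
smoothed-noise texture); SCC: irregular central mass (11–18 %, radius
modulated by angular harmonics, placed near the canvas center). The tight
box covers the region where the lesion field exceeds 30 % of its peak.
Every slice derives its RNG from (seed, class, case, slice), so studies are
byte-identical across runs. What passing tests therefore show is that the
pipeline — losses, attention, assignment, metrics, CV bookkeeping — works
end to end on well-separated lesions; they say nothing about contrast
regimes, anatomy, multi-lesion slices, or scanner variation in real CT.

The default registry reproduces the study arithmetic exactly: 429/44/119/243
cases of ADC/SCLC/LCC/SCC at 3/10/10/5 slices per case (1287/440/1190/1215
images) with the SCLC minority class doubled to 880 by augmentation. The
reduced profile used for training runs keeps the same structure at ~200
images (6/8/17/10 cases at 5/5/3/5 slices, SCLC doubled) — sized so a
5-fold run finishes in minutes on one CPU. Slice selection within a case is
the first-n rule, exposed separately because which slices the original
study took from each volume is not recoverable.

Augmentation composes a rotation about the image center with a translation;
images are warped bilinearly, boxes transformed as the axis-aligned
envelope of their rotated corners and clipped to the canvas. Parameter
ranges (θ uniform in ±15°, offsets uniform in ±10 % of the canvas) are
defaults — the transform formulas are fixed but no ranges are stated for
them. A draw that leaves no box on-canvas is redrawn (20 attempts, then an
error). Splits (8:1:1) and k-fold partitions operate at case level,
stratified by subtype, so slices (and augmented copies) of one case never
straddle a split.

## Training harness

Optimization defaults to Adam (lr 3e−3, weight decay 1e−4) with 2 warmup
epochs, cosine decay to 5 % of peak, gradient-norm clipping at 10, batch
size 8, 20 epochs; momentum SGD is available via `RunConfig.optimizer`.
Adam is the default because the 50-step single-image overfit check — the
smoke property that the optimization pipeline actually optimizes — needs
its faster transient. The model with the best validation mAP50 is
checkpointed per fold; the documented full-scale default is 100 epochs, but
no test depends on it. All randomness flows from the single `RunConfig`
seed. Non-finite losses abort the fold naming the epoch and batch.

## Numerical choices and limitations

- All arithmetic is float64 throughout the `nn` engine; oracle tolerances
  (1e−5 LSKA/LKA, 1e−6 SPPF-CA, 1e−9 box arithmetic) rely on this headroom.
- NMS and matching break confidence ties by stable sort order; metrics are
  guaranteed order-independent only for distinct confidences.
- The desk-scale layout fixes heads at strides (8, 16); other stride sets
  are rejected rather than silently mis-assembled.
- The engine is written for clarity at small scale, not throughput: im2col
  einsum convolutions on one CPU. Full-resolution training is out of reach;
  the desk-scale profiles are the supported regime.
- Checkpoints store config + weights in a self-describing `.npz`; no
  compatibility with any external detector's weights is attempted.
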