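# Methods

This package reimplements a lightweight single-stage detector for
recognising heat-stress behaviour in group-housed pigs, together with
the accounting tools (parameter/FLOPs profiler), the box-regression
losses, the posture+erythema decision rule, and a synthetic scene
generator that stands in for farm imagery.  This note records the model,
the conventions, and the design choices that were genuinely open.

## The detector

The skeleton is a nano-scale YOLOv12-style network: a convolutional
backbone whose two deepest stages use **area attention** (multi-head
softmax attention restricted to rectangular bands of the feature map,
with a depthwise 7×7 positional encoding), cross-stage partial blocks
(`C3k2`, `A2C2f`), an FPN/PAN neck, and an anchor-free dual-branch head
with distribution-focal box regression (`reg_max = 16`, three pyramid
levels at strides 8/16/32).  Because no deep-learning framework is a
dependency of this package, the layers, automatic differentiation and
the training loop are implemented directly on numpy; convolutions lower
onto BLAS matrix products via im2col and depthwise shift-accumulation.

Three modifications define the full model, each behind an independent
flag so the ablation variants can be built declaratively:

* **NAM channel attention** after the last backbone stage
  (256 channels).  A standalone batch norm supplies per-channel scales
  γ; the gate is `x · sigmoid(W_γ · BN(x))` with `W_γ = |γ_i|/Σ|γ_j|`.
  The absolute value makes the weights a probability vector even when
  BN scales go negative (the normalisation-attention reference
  convention).  An L1 penalty `p(Σ|γ|+Σ|λ|)` with `p = 1e−4` by default
  joins the training loss.  The spatial ("pixel normalisation")
  submodule is implemented and unit-tested but disabled by default: the
  channel-only insertion is the only configuration consistent with the
  +512-parameter budget of the attention insertion (2·256 for γ, β).
* **Rectangular self-calibration module (RCM)** after the second neck
  stage (the 64-channel P3 branch).  Horizontal and vertical mean
  pooling produce two axial vectors whose broadcast sum is a
  rectangular attention region; 1×11 and 11×1 depthwise strip
  convolutions (BN+ReLU between) recalibrate its shape; the sigmoid
  gate multiplies a 3×3-depthwise-refined copy of the input; batch
  norm, a ×2 inverted MLP and a layer-scale residual close the block.
  The strip kernel (11) and MLP expansion (2) are calibrated so the
  block carries exactly 19,072 parameters at 64 channels; both are
  config keys.
* **MBHead**: the localization branch's two standard 3×3 convolutions
  are replaced per level by a 1×1 stem into a narrow branch, two
  inverted-residual MBConv blocks (expansion 4, depthwise 3×3,
  squeeze-excitation, ReLU6), and the usual 1×1 projection to the
  4·`reg_max` distribution bins.  The per-level branch widths
  (26, 30, 14) and the SE squeeze width (10) are calibrated jointly
  against the head's printed parameter budget (−319,872 versus the
  baseline head) and its compute (≈0.48 GFLOPs at 640²; a 72.3%
  reduction).  The classification branch (two depthwise-separable
  pairs and a 1×1) is shared unchanged between variants.

## Counting conventions (and why they matter)

**Parameters.** `count_params` reports the *deployed* network: for
framework-style Conv blocks (conv + BN + activation) the batch norm is
folded into the convolution, so each contributes `weights + c_out`
scalars; standalone or custom-module batch norms (NAM, RCM, MBConv
internals) are exactly what a framework fuse pass leaves behind and
keep their γ/β pairs.  This is the convention under which YOLO-family
model summaries print their totals, and it is the convention that makes
the baseline at five classes come out at 2,557,703 with module deltas
+512 (NAM), +19,072 (RCM) and −319,872 (MBHead).

**FLOPs.** `count_flops` sums convolution multiply–accumulates over a
forward pass at a square input and doubles them (one multiply + one
add).  Elementwise work (BN, activations, biases, pooling) and the
attention tensor products are excluded — the convention of the
profiling hooks that YOLO tooling uses, calibrated once so the baseline
yields 6.3 GFLOPs at 640² and then applied unchanged to every variant,
so the deltas and ratios between variants are the trustworthy
quantities.  For reference, the area-attention matrix products would
add ≈0.5 GMACs at 640².

## Box losses

Boxes are corner-parameterised (x1, y1, x2, y2).  Alongside IoU and
CIoU (centre-distance penalty over the enclosing-box diagonal plus the
aspect term `(4/π²)(arctan(w_g/h_g) − arctan(w/h))²` weighted by
`α = m/(1−IoU+m)`; the squared difference is used, without which the
weighting formula is dimensionally inconsistent), the package
implements MPDIoU: IoU minus the squared top-left and bottom-right
corner distances, each normalised by the image diagonal `w²+h²`.  The
image extent is an explicit argument (`ImageExtent`), following the
original MPDIoU convention of normalising by the *input image* size.
`1 − MPDIoU` is the default regression loss; it is zero exactly at a
perfect match and its analytic gradient (exported for the recovery
tests) agrees with finite differences to 1e−4 away from ties.  MPDIoU
replaces CIoU in the loss only; the assignment metric keeps plain IoU.

## Training recipe

Full-scale defaults mirror the reference recipe: 100 epochs, batch 16,
mosaic on, mixup 0, copy-paste 0.1, image scale jitter ±0.5.  The
optimiser and schedule are unspecified upstream; SGD with momentum 0.9,
weight decay 5e−4 on convolution weights, linear warmup and a cosine
decay to 10% of the peak rate are adopted and recorded in
`TrainConfig`.  Target assignment is task-aligned: for each ground
truth, the top-10 in-box grid cells by `score^0.5 · IoU^6`; losses are
weighted 7.5 (box) / 0.5 (BCE classification) / 1.5 (distribution-focal)
plus the NAM penalty.

The **desk-scale preset** — the configuration every training-dependent
test runs — is 200 synthetic scenes at 320×320, 10 epochs, batch 2
(smaller batches give the short schedule more optimisation steps at the
same compute), learning rate 0.02, mosaic and copy-paste off.  A full
desk-scale run takes on the order of ten minutes on one CPU core and
reaches mAP@0.5 ≈ 0.75 on the separable synthetic data.  All
randomness flows from one seed; two runs with the same seed reproduce
their losses exactly.

## The synthetic pen generator

The generator emulates the statistical structure that the detector and
fusion rule depend on, not photographic appearance: five pose classes
with distinct silhouettes (elongated lying ellipses; standing bodies
with leg stubs; compact sitting blobs; eaters oriented into a trough
strip at the image top), partial pig-pig overlap (rejection sampling
caps pairwise occlusion at 55%), vertical fence bars drawn over the
animals, brightness/contrast variation, and an erythema signal.
Heat-stressed pigs are rendered in lying geometry with a redness value
drawn from Normal(0.08, 0.02) truncated to [0, 1]; other pigs draw from
Normal(0.02, 0.01) — more than two standard deviations of separation,
by construction.  The excess-red component is painted after lighting
and occlusion, scaled by the ratio of box pixels to the pixels the
animal still owns, so the *measured* redness index of each annotation
box equals its drawn value up to quantisation.  Consequently the
fraction of rendered stress pigs whose measured index exceeds the 0.05
threshold matches the truncated-normal tail Φ(1.5) ≈ 0.933.

What passing tests on this data do **not** show: robustness to real
pig appearance, fur/lighting interactions, camera perspective, or any
real-world detection accuracy.  The generator makes the pipeline's
logic testable; it cannot validate the biology.

Augmentation follows the stated recipe exactly — brightness ±30%,
contrast ±20%, one gray occlusion patch of at most 15% of the image
area (labels of occluded objects are kept), horizontal flip with
probability 0.5 — with ten copies per source image (710 source images
expand to 7,100).  Train/val splits are by scene, so augmented copies
never straddle the split.

## The fusion rule

A detection is heat stress iff the posture is lying-type AND the
redness index strictly exceeds the threshold (default 0.05,
`fusion.threshold`).  "Red channel value" is operationalised as the
excess-red index `mean(max(0, R − (G+B)/2))/255` over the box: a raw
mean red channel exceeds 0.05 on virtually any image, which would make
the threshold non-discriminative; excess red isolates vasodilation
from brightness.  The statistic is selectable via config.  At
inference the rule runs as post-processing over detections and can be
AND-combined with the model's own stress class (default) or used
standalone; both paths exist because the upstream protocol is
ambiguous about whether the rule is an annotation-time or
inference-time device.

## Numerical choices and degenerate inputs

* BN ε = 1e−5, momentum 0.1; weight init is Kaiming-normal from a
  dedicated seeded stream (`set_init_seed`).
* `nam_channel_weights` on an all-zero scale vector either raises or
  falls back to uniform, by configuration; the default raises.
* Evaluation matching is greedy per class in confidence order with
  index tie-breaks, AP by 101-point interpolation (11-point
  selectable); the confusion matrix adds a background row/column and
  conserves object counts.
* NMS is class-wise greedy at IoU 0.45 by default.
* Degenerate boxes (zero area, non-finite) are rejected at the type
  boundary (`Box`, `_coerce`).

## Known limitations

* The profiler's FLOPs are convention-calibrated; absolute GFLOPs are
  comparable only under the same convention (conv MACs ×2, attention
  excluded).
* The numpy training loop is single-process and CPU-bound; the
  full-scale recipe (640², 100 epochs, thousands of images) is not
  practical in it — it exists so the configuration surface matches the
  reference recipe, while the desk preset is the supported regime.
* The spatial NAM submodule fixes its input resolution at construction
  (per-pixel scales), so it is a unit-level feature, not part of the
  default detector.
* CIoU's aspect-term weight α is treated as a constant during
  differentiation (standard practice); the tensor CIoU path propagates
  no gradient through the aspect penalty itself.
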