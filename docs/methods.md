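# Methods

## Overview

`quanvit` implements a hybrid quantum–classical image classifier for
colonoscopy polyp frames: a four-stage bottleneck-residual backbone feeding a
vision transformer (ViT), built in two interchangeable modes. In *classical*
(cnn) mode every backbone operator is a trainable convolution; in *quantum*
(qnn) mode every convolution is replaced by a quanvolution — a sliding-window
operator whose kernel is an exactly simulated 4-qubit circuit with a frozen,
seeded rotation bank. Because the real clinical datasets the task comes from
are not redistributable, the package ships a parametric phantom generator
that reproduces their *structure* (four visually separable classes, class
imbalance repaired by two-stage augmentation, a reserved unseen test split)
and the full evaluation protocol (holdout + stratified 5-fold
cross-validation, per-class metrics, model-comparison reports, complexity
profiling).

## The quantum core

States are dense complex-double amplitude vectors over `2^n` basis states,
little-endian (qubit 0 = least-significant bit). Each normalized feature
`x ∈ [0,1]` is encoded on its own qubit as `Ry(πx)·Rz(πx)|0⟩` (Rz first);
the joint state is the tensor product. A linear CNOT chain
(0→1, 1→2, 2→3) entangles the qubits; an optional per-qubit Ry layer with
fixed seeded angles follows; the readout is the Pauli-Z expectation of each
qubit, `⟨Z_q⟩ = P(bit_q=0) − P(bit_q=1) ∈ [−1,1]`. All operations are
vectorized over arbitrary batch axes, so one call simulates every
(window, filter) pair of a quanvolutional layer at once. Useful exact limits
used as test oracles: with no entanglement and no variational layer,
`⟨Z_i⟩ = cos(πx_i)`; Rz alone never moves `⟨Z⟩` off `+1` on `|0…0⟩`.
Gradients of `⟨Z⟩` with respect to variational angles use the parameter-shift
rule `∂f/∂θ = [f(θ+π/2) − f(θ−π/2)]/2`, which is exact for rotation
generators.

Expectations (not sampled shots) are used throughout for determinism; shot
noise, density matrices and hardware backends are out of scope.

## Quanvolution

A quanvolutional layer maps each image window to 4 features by average-
pooling the window to a 2×2 grid (channels averaged first; odd extents share
the middle row/column; a 1×1 window replicates its value to all four
qubits), runs the encoding circuit once per filter with that filter's bank
angles, and writes `(1+⟨Z⟩)/2 ∈ [0,1]`. Two readouts exist: `mean_z`
averages the four qubit expectations into one channel per circuit (the
default), `per_qubit_z` emits all four. Filter diversity comes from a
`QuanvKernelBank`: per-filter Ry angles drawn once from a seeded RNG and
frozen, the standard way one small circuit yields a multi-channel map.
"Same" padding is symmetric zero padding with `ceil(size/stride)` outputs,
so the published stage geometry is reproduced exactly. Pooling between
quantum stages is classical channel-wise max pooling.

## Architecture

The backbone is the standard 3/4/6/3-block, 64/128/256/512-width bottleneck
layout (1×1 → 3×3 → 1×1 with expansion 4), stem 7×7 stride 2 + 3×3 stride-2
max-pool. On a 224×224×3 input at scale 1 the stages produce
56×56×64 → 56×56×256 → 28×28×512 → 14×14×1024 → 7×7×2048.

The final spatial map is tokenized one token per spatial cell through a
learned linear projection (49 tokens at full scale); learned positional
embeddings are added and a learnable CLS token is prepended. An optional 2×
nearest-neighbour upsampling switch gives the alternative 196-token reading
(the published patch-row arithmetic is inconsistent with a 7×7 map; both
readings are provided, neither asserted). Twelve pre-LayerNorm transformer
blocks (multi-head self-attention + GELU MLP) at dim 768 follow; the CLS
token passes through LayerNorm and a linear head to a 2- or 4-way softmax
(a single-logit sigmoid variant of the binary head is available behind a
flag).

A single `scale ∈ (0,1]` multiplier shrinks channel widths and the ViT
depth/width/heads together; `scale=1` reproduces the published geometry.
Backbone block counts do not scale (shallower variants trained worse).

### Classical mode

Convolutions use He fan-in init; every conv is followed by a trainable
per-channel batch normalization; the final norm of each block is
zero-initialized so blocks start as identity maps; downsampling shortcuts
are learned 1×1 stride-2 projections.

### Quantum mode

All backbone operators are frozen seeded quanvolutions, so the quantum
backbone contributes **zero trainable parameters** and acts as a fixed
deterministic feature extractor; only the transformer and head train, and
backbone features are computed once per image and cached during fitting.
Three stabilizers make a *frozen* 50-layer stack informative, all fixed
design (not fitted by gradient):

1. **Frozen per-channel renormalization** after every quanv operator:
   quanvolution outputs concentrate tightly around ½, so each layer's
   activations are re-spread as `clip(0.5 + 0.2·(x−μ_c)/σ_c, 0, 1)`, with
   `μ_c, σ_c` recorded from the first (training) batch and then frozen.
2. **Identity-dominant centred residual**:
   `out = norm(shortcut + 0.35·(path − ½))`. A frozen random path adds
   variance that would otherwise dilute the shortcut's information
   exponentially with depth (the frozen-network analogue of
   SkipInit/ReZero residual scaling).
3. **Parameter-free downsampling shortcut** (average-pool + channel
   tiling): a frozen random 1×1 circuit in the shortcut would scramble the
   identity path and defeat its purpose.

Before the ViT, features are z-scored per channel (again calibrated once on
the training batch and frozen) so their sample-to-sample variation reaches
the transformer on the scale its initialization expects.

Features therefore remain a deterministic function of
(config, quanvolution seed, training set); at fixed seeds repeated fits are
bit-reproducible.

## Training

Cross-entropy minimized with Adam (default lr 1e-3, betas (0.9, 0.99) —
the faster-adapting second moment matters at desk-scale step counts — batch
32, max 50 epochs, early stopping with patience 5 on validation loss, best
weights and normalization buffers restored). Gradients are clipped to
global norm 1.0; without clipping the small transformer is unstable at
these batch sizes. After each epoch of classical-mode training the batch-
norm statistics are re-estimated with one gradient-free pass over the
training set ("precise BN"); running averages otherwise lag the weights by
the EMA horizon, which at a handful of steps per epoch makes evaluation-
mode accuracy badly stale. All stochastic components (init, shuffling,
splits, banks) take explicit seeds.

The classical stack is trained by an in-package reverse-mode automatic
differentiation engine over numpy arrays (`quanvit.autograd`), providing
exactly the primitives the model needs (broadcast arithmetic, batched
matmul, im2col convolution, max pooling, reductions, shape ops); it is
verified end-to-end against central finite differences in the test suite.

## Evaluation

Metrics come from integer confusion matrices (rows = true class):
sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
NPV TN/(TN+FN), accuracy (TP+TN)/total; overall accuracy is trace/total;
K-class tables are reduced one-vs-rest per class. Undefined ratios (zero
denominators) are reported as not-available, never 0. Rounding is half-up
to two decimals at the report boundary only. Fold summaries use the sample
standard deviation (n−1): the published per-fold sensitivity rows reproduce
their printed 0.38 SD under this convention, and the multi-class overall
summary reproduces 97.94 ± 0.35; the published accuracy/specificity/NPV SD
entries (0.31/0.33/0.36) match neither the n−1 nor the population
convention and are treated as errata, not targets. Per-class "accuracy" in
the published multi-class tables often equals sensitivity; this package
defines it as one-vs-rest (TP+TN)/total and documents the divergence.
Cross-validation is stratified, disjoint and exhaustive over the train+val
pool (sklearn `StratifiedKFold`), one fresh model per fold; the reserved
test holdout is never touched. ROC curves/AUC use the standard threshold
sweep with trapezoidal area. Model comparisons report metric-wise B − A
differences (B = quantum model by convention).

## The phantom generator

Each frame is a pink mucosa field with a centred illumination vignette
(bright centre, smooth falloff to the border), meandering darker-red
vessel polylines, Gaussian sensor noise, and — for polyp classes — a
centred lesion with small positional jitter, emulating curated clinical
ROI framing. The lesion boundary is
`r(φ) = R·(1 + a_lob·cos(k_lob φ + φ0) + a_serr·cos(k_serr φ + φ1))`, with
a sigmoid radial edge of width `edge_softness`, a brightness dome, a
specular apex highlight and a rim shadow. Class-conditional parameter
ranges implement the ordinary meaning of the histological descriptors:

| class | radius | elevation | lobulation | serration | edge |
|---|---|---|---|---|---|
| hyperplastic | 0.08–0.12 | 0.45–0.60 | low | ~0 | soft |
| adenomatous | 0.16–0.20 | 0.60–0.80 | strong (k 3–5) | slight | sharper |
| serrated | 0.13–0.18 | 0.22–0.38 (flat) | low | strong (k 12–18) | sharp |

Boundary roughness (mean squared gray gradient in a band around the rim)
is ordered serrated > adenomatous > hyperplastic by construction, and a
class-mean template-matching baseline exceeds chance on both tasks,
certifying separability without deep training. The generator makes **no
claim of clinical realism**: it omits specular wet-surface highlights,
instrument artefacts, NICE/Paris morphology, inter-patient variation and
annotation noise, so passing desk-scale tests demonstrates that the
pipeline learns and evaluates correctly on separable data — not that the
published clinical accuracies transfer.

Augmentation is a fixed, versioned registry of exactly 21 named seeded ops
(flips, right-angle and small-angle rotations, translation, zooms, shear,
brightness/contrast/gamma/saturation changes, Gaussian and salt-pepper
noise, blur, sharpen, coarse cutout), each mapping a valid 8-bit RGB image
to one of identical shape. Two-stage balancing first equalizes per-class
counts by augmenting originals, then multiplies all classes to a stage-2
target. Splits reserve the unseen test set from originals first (preferring
originals without augmented derivatives), then stratify the remainder
80:20; a strict leakage guard keyed on origin-image id removes any
augmented derivative of a test original from train/val.

## Problem sizes

Desk-scale defaults: 32×32 phantoms, scale 1/8 models (≈250 k trainable
parameters in quantum mode, ≈620 k in classical mode), 200-image training
pools, 10-epoch sanity budgets. These sizes were chosen so the full test
suite and the acceptance script each complete comfortably on a single CPU
while still exercising every architectural component; `scale=1` rebuilds
the full published geometry for shape and complexity checks without
training it.

## Known limitations

* The published headline accuracies (98.18 % / 97.73 % binary, etc.) require
  the partly private clinical data and full-scale training; they are
  reproduced here only as worked-example arithmetic from the printed tables,
  not as model outputs.
* The frozen quantum backbone's informativeness depends on the calibrated
  renormalization; transferring a fitted model to data with a very
  different intensity distribution would require recalibration.
* The published stage table lists a 256×256×3 input yet 224-input stage
  arithmetic; the default input size is 224 so the printed shapes hold.
* Published totals of 86 M (quantum) vs 132 M (classical) parameters cannot
  be reconciled without knowing which components were trainable; the
  profiler reports what the constructed models actually contain and the
  FLOPs = 2×MACs pairing convention, and asserts nothing about the printed
  totals.
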