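# Methods

## Scope and design

The package provides the REM-ShuffleNetV2 architecture family and its
experimental harness as a library plus a thin CLI. The network itself runs
on a compact reverse-mode autodiff core written on numpy
(`remshuffle.nn`): tensors carry a tape of backward closures, and the
spatial kernels (grouped/depthwise 2-D convolution, max/avg pooling) are
im2col formulations with hand-written backward passes, each verified against
central finite differences in the test suite. float64 is used throughout —
at desk scale the clarity and testability of exact gradients outweigh the
memory savings of float32; the parameter report nevertheless quotes fp32
bytes (4 × parameter count), the size a deployed model would have.

## Architecture

**Units.** The basic unit splits its C channels in half, passes the right
half through 1×1 conv–BN–ReLU, 3×3 depthwise conv–BN, 1×1 conv–BN–ReLU and
(optionally) a channel-attention block, concatenates with the untouched left
half and shuffles with 2 groups. Batch norm follows every convolution; ReLU
is omitted after depthwise convolutions. The downsampling unit has no split:
a depthwise-led left branch and a pointwise-led right branch, both stride 2
and each producing half the output width, are concatenated and shuffled,
with attention at the right branch tail. "Repeats [2, 3, 2]" counts the
basic units per stage; each stage is additionally opened by exactly one
downsampling unit, so the stock configuration is [3, 7, 3].

**Residuals.** In basic units the shortcut is an identity added *after* the
channel shuffle (the skip sees the unit's final output) with no extra
activation after the add. In downsampling units the shortcut must change
both resolution and width; three projections are provided: `rm` (3×3 max
pool stride 2 → 1×1 conv–BN, the default), `ra` (average pool, identical
parameter count), and `rc` (3×3 stride-2 conv–BN, markedly more parameters
since the 3×3 kernel spans the full channel width). These orderings —
params(rm) = params(ra) < params(rc) — are asserted in tests.

**EDCA.** The per-channel descriptors are the spatial mean and *population*
standard deviation (divisor H·W, so a constant channel has std exactly 0).
The two descriptors pass through two *independent* bias-free 1-D kernels of
length K = |log₂(C)/γ + b/γ|_odd with γ = 2, b = 1; the sum is squashed by a
sigmoid and broadcast-multiplied onto the input. Independent kernels are the
natural reading of per-path learnable weighting; no additional scalar mixing
coefficients exist in the defining relation, so none are added. The
odd-size map truncates toward zero and bumps even values up to the next odd
integer (the established ECA convention); on power-of-two channel counts
from 2 to 4096 this coincides with "nearest odd, ties upward", and the
nearest-odd oracle is kept in the tests. 1-D convolutions use zero padding
K//2 so the output length stays C. At zero variance the std-path gradient
of √v is clipped (denominator floor 1e-12) so constant channels train
without NaNs. SE (bottleneck ratio 16 — a conventional default), ECA (the
avg path alone) and SRM (channel-wise fully connected over (mean, std))
serve as comparators behind the same `AttentionConfig` surface.

**Stems.** All stems map (N, 3, H, W) → (N, 24, H/4, W/4) so they are
drop-in interchangeable: Stem-A (3×3 s2 conv + 3×3 s2 max pool), Stem-B
(7×7 s2 conv + max pool), Stem-C (three stacked 3×3 convs, 12→12→24
channels, + max pool) and MSFEM. The schematic multi-scale stem is realized
as: shared 3×3 s2 conv to 24 channels, then a 3×3 s2 max-pool branch in
parallel with a (3×3 s1, 3×3 s2) conv branch, concatenated and fused by a
1×1 conv back to 24 channels. The parameter ordering MSFEM > Stem-C >
Stem-A, with Stem-B within the same order of magnitude of Stem-A, is
asserted; exact deltas are not, since the stem widths in the multi-scale
block are a free design choice.

**MDFEM** sits between Stage4 and the final 1×1 conv ("deep" placement):
parallel 3×3 and 5×5 same-padding branches at half the input width each,
concatenated and fused to the input width by a 1×1 conv; shape preserving.

**Head.** Final 1×1 conv to out_channels[3], global average pool, one fully
connected layer to the class logits. Softmax/cross-entropy live in the loss.

## Data pipeline

The reference manifest (22 classes, 6 crops) records per class the original
training count, augmented count, test count and integer expansion factor;
totals are 6732 / 22217 / 1676. The stratified split draws
floor(test_ratio·n) test items per class uniformly under the run seed —
the floor rule is the unique rounding consistent with all 22 reference
(train, test) pairs. Expansion factors are manifest data, not computed:
no closed-form rule reproduces them (one class stops at factor 2 with 894
images despite others reaching ≈1000+). Each original image contributes
itself plus factor−1 variants, ops cycled deterministically per image index
from the set {brighten ×1.3, darken ×0.7, rot90/180/270, free rotation in
[−30°, 30°], horizontal flip, vertical flip}; brightness clips to [0, 255],
free rotation uses reflective fill and preserves dimensions. The robustness
battery applies 15°/30° rotations, additive Gaussian noise (σ = 25 on the
0–255 scale) and brightness ×0.6 / ×1.4 — conventional mid-severity choices
where no canonical values exist.

## Training protocol

SGD with momentum 0.9 and weight decay 5e-4 applied to conv/linear weights
only (never batch-norm scales or biases — standard practice), batch size 32,
cross-entropy loss, cosine annealing lr(t) = lr_min + (lr0−lr_min)(1+cos(π
t/T))/2 from 0.01 to 1e-9 stepped per epoch, 60 epochs by default. The
"iterations" of the recipe are read as epochs, matching per-round accuracy
curves. Inputs are scaled to [0,1] then normalized with fixed constants
(mean 0.5, std 0.5 per channel). The best-test-accuracy epoch's weights are
retained and reloading them reproduces the recorded accuracy bit-for-bit.
Runs are fully reproducible under the config seed (seeded init, seeded
shuffling, no other randomness).

## Metrics

All metrics derive from the K×K confusion matrix with one-vs-rest counts.
Headline aggregates are macro (unweighted class means); support-weighted
aggregation is available behind a flag. Overall accuracy is trace/total —
the per-class one-vs-rest accuracy (TP+TN)/total is exposed per class but
never summed into a headline number, since averaging one-vs-rest accuracies
over many classes inflates the value. Indeterminate 0/0 ratios are defined
as 0 and emit a warning. Per-crop aggregation macro-averages the per-class
metrics within each crop's classes ({7, 3, 4, 2, 3, 3} classes over the six
crops). The implementation is cross-checked against a brute-force
per-sample tally and against scikit-learn in the tests; scikit-learn is
never the implementation.

## Synthetic data

The generator emulates field photographs at desk scale: an earthy textured
background with random distractor blobs, a green leaf ellipse with jittered
geometry and texture, and class-specific lesion disks (count, radius and
color ranges) placed entirely inside the leaf. Classes differ **only** in
lesion parameters; backgrounds and leaves follow the same law for every
class, so label signal lives exclusively in the lesions — verified by a
label-shuffle experiment that collapses accuracy to chance. Defaults: 4
classes (healthy + 3 lesion types), 100 train / 25 test per class, 64×64 px,
seed 0. The image size is far below field resolution (224 px); it keeps the
learning-sanity experiment within minutes on one CPU while preserving the
structure the pipeline needs. A 22-class manifest-shaped spec exercises
counting/manifest plumbing only. What passing synthetic tests shows: the
architecture, gradients, optimizer, schedule, metrics and data plumbing are
correct and a clearly separable lesion signal is learned quickly. What they
do not show: accuracy on real field imagery, which has far richer
within-class variation, occlusion, scale variation and label noise than any
of these renders.

## Problem sizes and numerical choices

The learning-sanity experiment trains the `tiny_preset` (stage widths
[24, 48, 96, 256], repeats [1, 1, 1], all REM features enabled) for 10
epochs — about a minute of CPU — and must exceed 0.9 test accuracy from a
chance-level start; the full 22-class, 224-px configuration is exercised
for shape contracts, parameter accounting and a gradient-flow smoke test
(every parameter receives a finite gradient; stem gradients are not
identically zero). Difficulty comparisons (easy vs hard specs, label
shuffling) use shorter 4-epoch runs at 60 images per class. Batch-norm eps
is 1e-5, momentum 0.1. Ties in max pooling resolve to the first window
position (argmax convention). Equation-level oracle comparisons use
tolerance 1e-5; gradient checks use central differences at 1e-6 with
rtol 1e-4.

## Known limitations

* No GPU path and float64 math: the full 224-px model trains far too slowly
  for real datasets; the toolkit targets correctness and desk-scale studies.
* Parameter counts are exact for this construction but published size
  tables for comparable models mix conventions (some including optimizer or
  serialization overhead), so only orderings and deltas are meaningful for
  comparison, not absolute megabyte figures.
* The synthetic generator is deliberately non-photorealistic; no simulation
  of specific diseases, lighting spectra or camera response is attempted.
* Class-activation visualization, pruning/distillation and third-party
  comparison architectures are out of scope.
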