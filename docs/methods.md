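# Methods

## Model

The classifier is a two-stream convolutional network over a ResNet50
feature extractor, specialized for single-sequence (T2-weighted) prostate
MRI slices. The backbone follows the standard ImageNet ResNet50 topology
with the classification top removed — stem (7×7/64 stride-2 conv, BN, ReLU,
3×3 stride-2 max-pool) and four bottleneck stages of 3/4/6/3 blocks — giving
7×7×2048 features for a 224×224 input and 23,587,712 parameters, of which
53,120 are batch-norm moving statistics. ImageNet weights can be loaded
from an `.npz` keyed by parameter name; by default the backbone is randomly
initialized (He-normal convolutions), which leaves every parameter count
unchanged. A requested-but-missing weight file raises rather than falling
back silently.

The two streams give the network simultaneous access to fine local texture
(3×3 kernel) and wider context (5×5 kernel plus depthwise 3×3), mimicking
how a reader scans both the suspicious focus and the gland as a whole. Both
stream convolutions use stride 1, 'same' padding and ReLU — the spatial
shape of the feature grid forces the stride and padding, while ReLU is the
conventional choice for an activation that carries no parameters and is
therefore not pinned by the parameter accounting.

### Channel-spatial attention (CSA)

Channel and spatial attention maps are computed from the same input and
applied jointly, `F_out = F ⊙ A_channel ⊙ A_spatial` (not sequentially in
the CBAM style; the product form of the fused map is taken literally). The
channel branch feeds both the global-average-pooled and global-max-pooled
channel statistics through one shared MLP (Dense C→C/r with ReLU and bias,
Dense C/r→C with bias) and sums the responses before the sigmoid; the
spatial branch concatenates the channel-wise mean and max maps and applies
a single biased k×k convolution and a sigmoid. The internal hyperparameters
are not free: with C = 256, the block's published parameter count of 16,771
is matched exactly, and only by, reduction r = 8 and spatial kernel k = 7
with biases on all layers (16,672 channel + 99 spatial). The parameter
count follows the closed form `C·C/r + C/r + C/r·C + C + 2k² + 1`.

### Fusion

Cross-stream fusion keeps each stream's additive contribution plus their
elementwise interaction, `BatchNorm(S1 + S2 + S1⊙S2)`; the batch
normalization (1,024 parameters at C = 256, half of them moving statistics)
is the only normalization applied. Adaptive feature fusion then gates the
fused map, `ReLU(conv_T(F)) ⊙ σ(conv_G(F))`; 1×1 convolutions with bias are
likewise the unique standard choice reproducing the published 131,584
(= 2·(256² + 256)). Outputs are therefore nonnegative and bounded by the
transformed magnitude — the gate acts as per-element soft switches.

### Head and decision

`[GAP; GMP]` concatenation (average first) gives a 512-vector descriptor,
followed by Dense(512, ReLU), Dropout(0.4), Dense(256, ReLU), Dropout(0.3)
and a sigmoid unit. The decision threshold defaults to 0.5 with the ≥
convention and is configurable. Total accounting: 41,976,967 parameters,
41,923,335 trainable; the non-trainable 53,632 are the backbone's plus the
fusion layer's batch-norm moving statistics.

## Computational substrate

No deep-learning framework is a dependency: the package carries a compact
reverse-mode autodiff engine on NumPy arrays (NHWC layout) implementing the
operations the architecture needs — im2col convolutions, depthwise
convolution, max pooling, reductions, broadcasting arithmetic, sigmoid/ReLU
/log, batch normalization composed from primitives. Correctness is
established by central-difference numeric-gradient tests per operation and
through a composed CSA→BN→AFF block (max error ~1e-10 at float64).
Batch normalization uses momentum 0.99 and epsilon 1e-3; Adam uses betas
(0.9, 0.999) and epsilon 1e-7. Gradient tie-breaks: max-reductions route
the gradient to the first maximum. All computation is float64.

## Training protocol

Two stages. Stage 1 (default epochs 1–25) freezes the backbone — its
weights, including batch-norm statistics, are bit-identical afterwards —
and trains the streams, attention, fusion and head with Adam at lr 0.001
under binary cross-entropy (probabilities clipped at 1e-7). Validation AUC
is the monitored metric, improvement meaning strict increase (min-delta 0):
early stopping after 7 non-improving epochs, learning rate halved (factor
0.5) after 3, with the plateau counter reset on each reduction. Stage 2
(epochs 26–50) unfreezes the whole backbone at lr 0.0001 with patiences 10
and 7. Best-monitored weights are restored at each stage end. Runs are
deterministic given the model seed (initialization, dropout) and trainer
seed (shuffling).

**Batch-norm calibration.** A randomly initialized backbone starts with
moving statistics (mean 0, variance 1) that do not describe its actual
activations; in the frozen stage its batch-norm layers run in inference
mode, so features reach the trainable part arbitrarily scaled and training
stalls (observed: validation AUC ≈ 0.5). A pretrained backbone ships with
calibrated statistics; its random-weight counterpart must therefore be
calibrated explicitly. `training.calibrate_batchnorm` runs a few
deterministic forward passes that update only the moving statistics (no
learnable weight changes) and is called once before stage 1. Keeping it
outside `train_two_stage` preserves the exact freeze contract during
training.

Cross-validation uses stratified k-fold (optionally patient-grouped via
grouped stratification); dispersion across folds is reported as the sample
standard deviation (ddof = 1). Class weighting is not applied — the
intended cohorts are near-balanced.

## Data handling

Series selection keeps a slice if its DICOM series description matches,
case-insensitively and exactly, one of seven transverse T2 acquisition
protocol names (fat-suppressed, turbo-spin-echo and HASTE variants;
extensible allowlist) and the series is transverse/axial. Preprocessing is
per-slice min–max rescaling to [0, 255] (a constant slice maps to zeros),
bilinear resize to the network input size, grayscale replication to three
channels, and subtraction of the ImageNet channel means as an additive
offset — the min–max step makes that offset meaningful for arbitrary MRI
intensity scales. Augmentation (training only) applies horizontal flip
(p = 0.5), rotation uniform in ±15° and central zoom uniform in ±10%, in
that fixed order for reproducibility.

Splitting supports two modes. Patient-grouped (default): whole patients are
assigned, per label, to the subset with the largest relative shortfall of
its slice quota — no patient ever spans subsets. Slice-level: exact global
subset sizes by largest-remainder rounding with per-label counts within one
sample of the stratified target (e.g. fractions 0.6982/0.1496/0.1522 of
3850 slices give exactly 2688/576/586). The slice-level mode exists to
reproduce slice-count bookkeeping; the grouped mode is the leakage-safe
default.

## Synthetic phantoms

The generator emulates what a slice-level classifier sees in a transverse
T2 prostate study, not MR physics: a smooth elliptical gland
(intensity 150) on a dark background (40), softened boundary (Gaussian
σ = 2 px), a long-wavelength intensity field (σ = 0.15·image size, sd 12)
standing in for coil inhomogeneity, and per-pixel Gaussian noise (sd 8).
High-suspicion slices add a focal hypointense disc (offset −60, radius
5–10% of the image) with fine-grained interior texture (5% of the
contrast), placed fully inside the gland and clear of the smoothed
boundary. Contrast −60 against noise 8 makes the task separable by
construction — a darkest-local-mean statistic splits the classes perfectly
— so training smoke tests measure optimization, not task ambiguity. Each
record carries the gland, eroded gland-core and lesion masks as ground
truth; all randomness derives from (spec, seed) with separate streams for
gland, texture, lesion and noise, so a class-1 phantom with zero contrast
and zero noise is pixelwise identical to its class-0 counterpart.

What the phantoms do not model: anatomy (zonal structure, rectum, bladder),
acquisition artifacts, inter-scanner variation, PI-RADS ambiguity
(borderline lesions), or hyperintense pathology. Passing phantom tests
therefore demonstrates that the architecture, training protocol and
explainability machinery function and can fit a localized-darkness task;
it says nothing about clinical performance.

## Grad-CAM

The class score is the pre-sigmoid logit, negated for predicted-negative
cases so the map always shows evidence for the predicted class. Channel
weights are spatial means of the score gradient at the target layer; the
weighted channel sum is rectified, bilinearly upsampled and min–max
normalized (an all-zero map stays zero, with a warning). The heatmap is
invariant to positive rescaling of the final-layer logit.

**Default target layer.** Any captured block output can be targeted. The
default is the local stream's attention output rather than the fusion
output: measured on fully trained phantom models across several seeds and
cohort sizes, the fused/AFF-level CAM localized the lesion in anywhere from
26% to 99% of correctly classified positives — hypointense-lesion evidence
often enters the fused representation with negative sign and is removed by
the CAM's rectification — while the local-stream CSA output localized in
94–99% of the same runs. For a method whose purpose is showing clinicians
*where* the evidence is, the reliable layer is the right default; the
fusion output remains selectable by name.

## Problem sizes in the test suite

The full 224-px, 42M-parameter graph is built for accounting and shape
checks and run forward once; training-based tests use a reduced
configuration (64-px input, width-8 streams, a three-block width-8/16
backbone, CSA reduction 4 with kernel 3, 16/8 head) on a 200-slice phantom
cohort (40 patients × 5 slices, batch 16), which takes the full two-stage
protocol in well under a minute on one CPU. Protocol-enforcement tests
additionally use scripted validation metrics to pin the exact
halving/patience cadence independently of optimization noise.

## Known limitations

* CPU-bound NumPy training makes the canonical 224-px configuration
  impractical to train here; it is exercised structurally and by forward
  passes. The reduced configuration shares every code path.
* No ImageNet weights are bundled; transfer learning from actual pretrained
  features requires supplying a weight archive.
* The AUC/AP implementations delegate the curve sweeps to scikit-learn;
  the package's own contribution there is the contract (undefined-metric
  handling, tie semantics) and its verification against a brute-force
  pair-ranking oracle.
* Binary classification only; PI-RADS 1–5 grading, 3-D volumes and lesion
  segmentation are out of scope.
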