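# Methods

## Problem and data model

The package segments glioma sub-regions on 2-D axial slices of
co-registered, skull-stripped, multi-modal MRI. A case is a 4-channel
volume in fixed modality order (T1, T1c, T2, FLAIR); the label mask uses
{0 background, 1 edema, 2 core, 3 enhancing}, evaluated through the nested
BraTS regions WT = {1,2,3}, TC = {2,3}, ET = {3}. Training is strictly
per-slice (2-D): the network's input/output contract is a single padded
slice, which is the only reading consistent with a 2-D input of
256 × 256 × 4. Upstream preprocessing (rigid co-registration, skull
stripping, bias-field correction) is assumed done by the standard external
tools and is out of scope.

### Intensity normalization

Per modality and per volume, intensities are min–max mapped to [0, 1] over
brain voxels only, where the brain mask is "nonzero in any modality";
background stays 0 and a constant modality maps to all zeros (0/0 guard).
Robust percentile clipping is deliberately not applied by default — the
plain min–max reading is the simplest one consistent with "a standard
range of 0 and 1". The normalization is idempotent for continuous-valued
volumes; a pathological volume in which some voxel is the per-modality
minimum of *every* modality simultaneously could change the brain mask on
a second pass, which we accept rather than carrying an explicit mask
through the API.

### Slice extraction

240 × 240 slices are zero-padded symmetrically to the network size
(default 256; 8 pixels per side) rather than resampled, so label geometry
is preserved exactly and cropping the margin recovers the input
bit-for-bit. Slices with empty masks are dropped for training and kept for
inference.

## Handcrafted features

**Dense SURF.** Keypoints lie on a regular grid with step *s* (default 8);
no interest-point detection is performed, so the Hessian responses
(L_xx, L_xy, L_yy at scale σ) are exposed only as diagnostics. At each
keypoint, first-order Gaussian-derivative responses (σ = 1.6, exact
Gaussian filters rather than box approximations — exactness beats speed at
this scale) over a 16 × 16 support window are partitioned into 4 × 4
sub-regions, summarized as (Σdx, Σdy, Σ|dx|, Σ|dy|) each, and
L2-normalized: the classic 64-dimensional variant (the 128-dimensional
one is not implemented). Orientation assignment
θ = arctan2(Σ W·L_x, Σ W·L_y), with a Gaussian weight W and the window
rotated by θ, is implemented but off by default — dense grids typically
skip it and nothing downstream depends on it. Keypoints whose support
exceeds the image are skipped with a logged count. To feed descriptors to
the network, each pixel takes the vector of its nearest keypoint
(piecewise-constant 64-channel upsampling); this descriptor-to-channel
conversion is a package design choice.

**HOG.** Central-difference gradients ((f(x+1) − f(x−1))/2, borders
edge-replicated); magnitude hard-assigned to one of 9 unsigned angular
bins over [0°, 180°) per 8 × 8 cell; 2 × 2-cell blocks L2-normalized with
ε = 1e-6 (v/√(‖v‖² + ε²), so a constant image yields an exactly zero
vector). These are the canonical published defaults; all are
configurable. The per-pixel channel maps broadcast each cell's raw
histogram to its pixels.

**Texture/intensity maps.** Sliding-window (default 7 × 7) mean, median
and standard deviation; GLCM contrast, homogeneity and energy from a
symmetric, normalized co-occurrence matrix over 8 equal-width quantization
levels of [0, 1] (offsets configurable, default horizontal); and an
8-neighbour LBP code map using neighbor ≥ center (constant image → 255),
scaled to [0, 1] as a channel. Per-pixel GLCM features are computed
exactly via per-code indicator images and uniform filters, not by
approximation.

Features are extracted from one source modality, FLAIR by default, where
tumor regions are most conspicuous; the choice is configurable. The
"shape-based" family (area, perimeter, compactness) requires an already
segmented object and therefore cannot serve as an input feature; it is
excluded.

## Network

A U-Net-style encoder-decoder. Encoder stage *i* (i = 0..3): two 3 × 3
convolutions + ReLU at width (64, 128, 256, 512)ᵢ, then 2 × 2 max pooling.
A double-convolution bottleneck keeps the deepest width (512). Decoder
stage *i*: nearest-neighbour ×2 upsampling, 3 × 3 convolution to width i,
concatenation with the stage-i encoder skip, and a second 3 × 3
convolution. A 1 × 1 convolution maps the final 64-channel map to 4
classes with per-pixel softmax; argmax ties break toward the smaller class
index. Input sizes must be divisible by 2⁴. The published layer table
this follows lists spatial sizes that are not mutually consistent (plain
convolutions changing resolution, jumps of ×4); since the design is
declared U-Net-based, the channel progression, 4-channel softmax head and
256 × 256 × 4 input/output are honored exactly while spatial sizes follow
one halving per encoder stage and one doubling per decoder stage, with
skip connections included. Batch normalization is off (the recipe is
silent); weights are He-initialized; everything is float32.

### Fusion variants

* `input_channel`: handcrafted channels join the 4 modalities at the first
  convolution (4 + k inputs).
* `feature_map`: the stack is average-pool-downsampled (average rather
  than nearest-neighbour, which would alias texture channels) to the
  resolution after encoder stage *d* and joins that stage's pooled output;
  the next convolution sees c_d + k inputs.
* `decision_level`: the stack joins the last 64-channel decoder map; the
  classifier sees 64 + k inputs.

Fused convolutions are implemented as two paths — the shared backbone
weight plus a separate fusion weight on the handcrafted channels, summed —
rather than one widened kernel. This makes weight sharing with a trained
baseline exact and makes the zeroed-fusion ablation reproduce the baseline
output bit-for-bit (a single widened matrix multiply would change BLAS
accumulation order and drift in the last ulp).

## Training

Loss: `L = CE + (1 − softDice)` with CE the pixel-mean categorical
cross-entropy (probabilities clipped to [1e-7, 1]) and softDice the
smoothed ratio (2Σyp + ε)/(Σy + Σp + ε), ε = 1e-6, averaged over the three
foreground classes only (background excluded, configurable) and computed
over the whole minibatch per class. As printed, the source recipe's Dice
equation defines the *loss* (1 − ratio); composing it literally with the
"(1 − Dice)" total would reward low overlap, so the only reading under
which a perfect prediction minimizes the loss is used.

Optimization: minibatch SGD with momentum 0.9, weight decay 5e-4 applied
to weights (not biases), learning rate 1e-3, batch 16, up to 100 epochs —
these are the defaults of `TrainConfig`. Early stopping monitors
validation loss (10 % of the training cases, seeded) with patience 10 and
min-delta 0, restoring the best-validation weights; patience is a package
choice, as is best-weight restoration. The hybrid path is initialized
from the trained baseline (shared weights copied, fusion weights zeroed so
fine-tuning starts exactly at baseline behavior) and fine-tuned at lr/10
for at most 50 epochs; training the hybrid from scratch is also possible
but the fine-tuning path is the documented default.

The whole stack — forward, backward, update — runs on a small reverse-mode
autodiff core over numpy (im2col convolutions, explicit layer backwards,
a fused softmax + CE + Dice gradient verified against finite differences).
Single-threaded runs are bit-reproducible given the seeds.

### Augmentation

Applied jointly to image and mask with one seeded generator per pair, all
draws consumed in a fixed order (geometric → intensity shift → contrast)
so determinism is trivial to audit: rotation ±15°, scale 0.8–1.2 (both
about the center, bilinear for intensities, nearest-neighbour for labels,
zero padding), horizontal flip p = 0.5, elastic deformation (white noise
filtered with a σ = 4 Gaussian, rescaled so the peak displacement is α,
default 10 px — α is not specified by the source recipe), intensity shift
±0.1 with clipping to [0, 1], and per-channel global histogram
equalization applied with probability 0.5 (the recipe does not say whether
it is applied always; 0.5 is configurable). Nearest-neighbour mask warping
guarantees no interpolation-invented labels.

## Evaluation

From per-region confusion counts: accuracy (TP+TN)/total, Dice
2TP/(2TP+FP+FN), sensitivity TP/(TP+FN), specificity TN/(TN+FP). Regions
empty in both truth and prediction score 1.0 for the affected metric and
0.0 otherwise (BraTS-style convention; the source is silent). Dataset
metrics are per-case macro means; per-case values are retained in the
report. The split helper uses round(fraction·n), reproducing the 70:30
convention of 285 → 200/85.

## Phantom generator

Each phantom emulates one normalized, skull-stripped slice: an elliptical
brain (randomized axes) carrying a smooth Gaussian-filtered noise texture
(scale 4 px, amplitude 0.1), and a deformed disc tumor (radius drawn from
size/8–size/4, low-order angular harmonics up to 24 % radial deformation)
with an enhancing rim (label 3, thickness 2 px) on a core disc (label 2)
inside an edema annulus (label 1, half the tumor radius). Modality
offsets qualitatively mimic glioma contrast — FLAIR/T2-bright edema,
T1-dark tumor, T1c-bright rim (e.g. FLAIR +0.35/+0.25/+0.30 for
edema/core/rim) — with additive Gaussian noise (σ = 0.05) and clipping to
[0, 1]. Item seeds derive from SeedSequence([seed, index]), so datasets
are order-independent.

What the phantoms do *not* emulate: anatomy (gyri, ventricles, tissue
classes), multi-focal or infiltrative lesions, bias fields, scanner
variation, 3-D continuity, partial-volume boundaries. Passing tests
therefore demonstrate the correctness and trainability of the machinery
— descriptors, losses, fusion, optimization — not clinical-grade accuracy;
real-data performance must be established on real data.

## Desk-scale recipe and problem sizes

Tests and the acceptance script run a reduced configuration chosen to keep
a full run in minutes on one CPU: 64 phantoms at 64 × 64, encoder widths
8/16/32/64, HOG-only fusion (9 channels). At this scale an epoch is ~4
SGD updates, so the full-scale learning rate of 1e-3 cannot converge from
random initialization within a 30–60-epoch budget; the demo recipe uses
lr 0.02 with early-stopping patience equal to the epoch budget, because a
6-slice validation loss is too noisy for a short patience. These are
choices about the demo problem size, not changes to the method's defaults.

## Numerical notes and limitations

* Probabilities are computed in float64 at the softmax even though the
  network is float32; CE clipping bounds the loss at −ln(1e-7) ≈ 16.1.
* Max-pool ties take the first (row-major) element; argmax ties take the
  smaller class index.
* GLCM window features normalize by the per-window valid-pair count, so
  border windows are exact, not zero-padded approximations.
* Offline augmentation (appending augmented copies) is provided instead
  of per-epoch online augmentation; with the small demo datasets this is
  the cheaper and equally effective option.
* The full-size network (19.6 M parameters, 256 × 256 input) runs at
  ~12 s per slice forward on one CPU core — usable for verification, not
  for production-scale training, which is the expected trade-off of a
  pure-numpy engine.
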