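# Methods

## Pipeline

`histotile` classifies whole pathology images as benign or malignant in
four stages:

1. **Grid division.** An image of height H and width W is cut into an n×n
   grid, n ∈ {1, 2, 4}. Boundaries follow the even-partition rule
   b_k = ⌊k·D/n + ½⌋ for k = 0…n along each dimension, which yields
   near-equal tiles and an exact cover for any shape (the canonical
   700×460 acquisition frame divides evenly for n ∈ {2, 4}). Tiles are
   ordered row-major and each inherits the parent image's label; training
   on tiles therefore multiplies the labeled set by n². Stitching the
   tiles back reconstructs the image exactly — this conservation property
   is asserted by randomized tests.

2. **Frozen feature extraction.** Every tile is resized (bilinear) to the
   backbone's input size, scaled to its expected value range, and mapped to
   a fixed-length feature vector. The backbone is constructed once and
   never updated: extracting features from the same tile is byte-identical
   before and after head training. Two backbones implement the plug-in
   contract (`name`, `input_size`, `output_dim`, `extract(batch)`):
   * `InceptionResNetV2Backbone` — the ImageNet-pretrained network with its
     final fully connected layer removed and the last feature map globally
     average-pooled to 1536 dims; inputs are 299×299 RGB in [−1, 1]. It
     requires a deep-learning runtime and raises an explicit error naming
     the fixture fallback when none is importable.
   * `FixtureBackbone` — a seeded random linear projection (with bias) of
     the 32×32 grayscale downsample of the input, 64 dims, values in
     [0, 1]. It is fully deterministic, needs no downloads, runs in
     milliseconds per tile, and is the default in tests and the acceptance
     script.
   Extracted features can be cached to a keyed archive (backbone name,
   output dim, tiling n, manifest fingerprint, record count in the header);
   loading verifies the key so stale features are never reused silently.

3. **Trainable head.** A fully connected network d → 1024 → 512 → 2 with
   ReLU on the hidden layers and a softmax output, fit on tile features
   with the mean cross-entropy loss (probabilities clipped at ε = 1e−12).
   Optimization is Adam with bias correction; defaults are learning rate
   0.001, β₁ = 0.9, β₂ = 0.999, batch size 32. Data are reshuffled every
   epoch with a seeded generator and the last partial batch is kept.
   Forward, backward and the optimizer are a self-contained NumPy
   implementation; analytic gradients are verified against central finite
   differences to 1e−5 in the test suite, and with β₁ = β₂ = 0 and no bias
   correction the update reduces to the rescaled gradient step
   lr·g/(|g| + ε) (a tested limit). Initialization is He-scaled and
   seeded. The epoch budget (default 100) and early stopping on a
   training-loss plateau (patience 10, min delta 1e−4) are this package's
   choices — no regularization is applied by default. Softmax uses
   max-subtraction, so it is overflow-safe and exactly shift-invariant.

4. **Average fusion.** The K = n² per-tile probability pairs of one image
   are averaged componentwise and the arg-max class is returned; the mean
   of distributions is a distribution, and since summing and averaging
   differ by the positive factor K, "sum then arg-max" and "mean then
   arg-max" give identical labels (property-tested on 10⁵ random cases).
   With n = 1 the pipeline reduces bit-for-bit to single-image
   classification. An exact tie (0.5, 0.5) resolves to **malignant**,
   favoring sensitivity in a screening context; the rule is stated in the
   CLI help. Fusion only ever combines the tiles of one image — there is
   no cross-image or multi-model ensembling.

## Data handling

Records are read either from the BreaKHis convention
(`<BIOPSY>_<CLASS>_<SUBTYPE>-<SLIDE>-<MAG>-<SEQ>.png`, with directory-name
fallback for the magnification) or from generic `benign/`–`malignant/`
folders, in deterministic sorted-path order. Splitting is whole-image
(every tile of an image lands in one partition), stratified by label by
default, and reproducible: records are ordered by path before the seeded
shuffle, so splits are stable across filesystems. Per label, the test
partition takes ⌊(1−f)·n⌋ records and the train partition the remainder
(equivalently, train = ⌈f·n⌉). This rounding convention reproduces the
published per-magnification 80/20 distribution exactly, e.g. 625 → 500/125
and 644 → 516/128; the realized train fraction deviates from f by at most
one record per label. An optional `group_by_patient` mode keeps all images
of one patient in one partition (off by default — the reference protocol is
image-level). Evaluation is image-level only.

Routine photometric/geometric augmentation (horizontal/vertical flips,
scaling 0.9–1.1 with reflect-pad/center-crop back to the original frame,
rotation ±30° with reflect padding, per-channel gain 0.9–1.1, additive
Gaussian noise σ = 5 on the 8-bit scale) applies to training images only
and preserves label, metadata and shape; it expands each image by a fixed
factor (default 4: the original plus three seeded random variants). The
operation set is named in the reference protocol but its parameters are
not; the ranges above are this package's defaults. Routine augmentation
and grid division are alternative strategies — the ablation harness maps
none → (no aug, n=1), routine → (aug, n=1), quarter → n=2,
sixteenth → n=4 — and are not composed by default.

## Metrics

Accuracy, Precision, Recall and F1 are computed as exact rationals
(`fractions.Fraction`) from the confusion counts and rounded half-away-
from-zero to two-decimal percentages; malignant is the positive class.
MCC's numerator and the product under its square root are exact integers;
the square root is the one irrational step, taken in double precision
(error ~1e−13, far below the printed precision). Degenerate denominators
return 0 by convention (precision with no positive predictions, recall
with no positives, F1 with both undefined, MCC with a zero factor under
the root) and log a warning. The implementation is checked against an
independent Fraction/50-digit-Decimal oracle on random matrices and by
exhaustive enumeration over all 2⁸ labelings of 8 items.

## Synthetic data

The generator emulates the structural assumption behind label-inheriting
tiles. Images are a light tissue-like background (level 205) with Gaussian
pixel noise (`noise_sigma`, default 10) plus a class texture of amplitude
`class_separation` (default 30, 8-bit units): benign images get smooth
zero-mean low-frequency blobs (Gaussian-filtered noise, correlation length
8 px) with a pink tint; malignant images get sparse dark high-frequency
speckle (density 0.12, depth 3× the amplitude) with a purple tint,
emulating hyperchromatic nuclei — denser hematoxylin staining in malignant
fields is the realism argument for the darker class. In **stationary**
mode the texture covers the frame, so every tile carries class signal; in
**focal** mode it is confined to a random rectangle of area
`focal_fraction` (default 0.25), so inherited tile labels are noisy — the
generator records the signal rectangles and reports realized per-tile
signal coverage for assertions. With `class_separation = 0` the classes
are distributionally identical (the null). Default desk scale is 100
images/class at 128×128, which keeps end-to-end tests in seconds; the
(460, 700) BreaKHis frame is used for geometry tests only.

What passing on this data shows — and does not. The textures are chosen so
the fixture backbone's features separate the classes (both mean luminance
and smoothness survive the 32×32 downsample, and the ReLU head converts
variance differences into mean differences), so end-to-end recovery tests
are well-posed. The generator does not model real H&E morphology, stain
variation, inter-patient heterogeneity or class imbalance; passing the
synthetic criteria validates the machinery (tiling, freezing, training,
fusion, scoring), not clinical performance on real slides.

## Verification problem sizes

The acceptance script evaluates the published 40× sixteenth-division
confusion matrix (274/1/124/0 — the only magnification whose narrative and
printed metrics are fully consistent), realizes the stratified splits at
the published cardinalities (7909 stub records), and runs the end-to-end
recovery at 100 images/class (stationary, strong separation) and 500
images/class (null, so the 20 % test partition holds 200 images and the
chance band is a binomial ±3.5 σ ≈ ±12 points). Property checks use 1000
random image shapes for tiling conservation, 10⁵ random cases for fusion
equivalence, 1256 matrices/labelings for the metrics oracle, and ~50
coordinates for the gradient check. These sizes are the package's desk-
scale choices; they complete in a few minutes on one CPU.

## Known limitations

* Headline results on the real BreaKHis corpus require the external
  dataset and a pretrained Inception-ResNet V2 at scale; neither is
  bundled. The pipeline accepts them unchanged through `scan_dataset` and
  the backbone plug-in contract.
* The realized metrics of a random 80/20 split depend on the split seed;
  no canonical seed is published, so only split *counts*, not memberships,
  are reproduced.
* No stain normalization, no overlapping/sliding-window patching, no
  weighted or learned fusion, no probability calibration, no patient-level
  scoring, no ROC/AUC.
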