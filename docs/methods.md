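# Methods

This note documents the models, numerical choices and limitations behind
`acetoseg`. It is written for a reader who wants to understand *why* the
package computes what it computes, and what a passing test suite does and
does not demonstrate.

## Problem setting

During colposcopy, acetic acid is applied to the cervix; cervical
intraepithelial neoplasia (CIN) transiently turns white ("acetowhite
epithelium"), while normal squamous epithelium that is *already* near-white
does not change but looks the same in the post-application image. A
segmenter that sees only the after-image therefore cannot, even in
principle, distinguish "white because it whitened" from "white all along".
The method implemented here gives the network both images — the
after-image and the before-image projectively aligned onto it — so that
the *change* becomes a learnable per-pixel feature. Everything else
(architecture, loss, evaluation protocol) is kept deliberately plain so
the comparison between the dual-input arm ("proposed") and the
after-image-only arm ("control") isolates the value of the before-image.

## Alignment model

The cervix surface is treated as approximately planar between the two
exposures, so the geometric relation between before- and after-images is a
plane projective transformation (homography). The assumptions are: rigid
scene, small time gap, camera pose change only; the *color* change caused
by acetic acid is exactly what must *not* be removed by alignment.

Estimation is the normalized direct linear transform: both point sets are
translated to their centroid and scaled so the mean distance from it is
√2 (Hartley normalization), the 2N×9 design matrix is solved by SVD, and
the result is denormalized. With four nondegenerate noiseless
correspondences this is an exact interpolant; with more, the algebraic
least-squares solution. Degeneracies (duplicate points, three collinear
points among the first four, rank-deficient design) raise typed errors
naming the offending point labels.

Conventions fixed throughout the package:

* coordinates are 0-based, x rightward (column), y downward (row), pixel
  centers at integer coordinates;
* homographies map before→after and are normalized to h33 = 1 when
  |h33| > 1e-8, otherwise to unit Frobenius norm;
* warping is inverse mapping (iterate output pixels), bilinear for
  images, nearest-neighbour for masks (so masks stay binary), fill 0.
  Bilinear interpolation for the deformed before-image is this package's
  choice; nothing hinges on it.

Correspondences come from a plain-text file (`label x_before y_before
x_after y_after` per line) because the clinical workflow identifies them
by eye; the synthetic generator emits exact landmarks instead.

## Network and training

The segmenter is a U-Net: a contracting encoder, an expanding decoder,
and skip connections at every resolution level, ending in a 1×1
convolution with a per-pixel sigmoid. The dual-input arm takes 6 channels
(after RGB, aligned-before RGB), the control arm 3. Training minimizes
soft dice loss

    L = 1 − (2·Σ p·t + s) / (Σ p + Σ t + s),

averaged per sample over the mini-batch, with Adam. The smoothing constant
s (default 1.0) only regularizes the empty-mask corner case; for binary
inputs and s→0, 1−L is exactly the F1 score, an identity the test suite
asserts to 1e-12.

Two encoder recipes exist:

* `small` (default): `depth` resolution levels of width
  `base_channels·2^level`, two 3×3 convolutions per encoder level; each
  decoder level upsamples (nearest, 2×), concatenates the skip tensor and
  applies one 3×3 convolution. Defaults: depth 3, base 3 (≈4k
  parameters). This width was chosen so that the full repeated-LOOCV
  comparison runs on a single CPU core in minutes while still saturating
  the synthetic task; the dual-vs-single comparison is architecture-
  agnostic, which is the point of the study design.
* `vgg16_style`: the 13-convolution VGG16 channel layout (64–512, five
  levels) with a two-conv decoder, for full-scale runs. No pretrained
  weights are bundled; when a 6-channel stem must be built from a
  3-channel initialization, `replicate_halve` replicates the kernels
  across the extra channels and halves them, preserving expected
  activation magnitude (the alternative is plain random init).

The engine is written directly in numpy + numba (channels-first float32;
convolutions as width-vectorized compiled loops; backpropagation derived
by hand, with the input gradient expressed as a convolution with the
flipped, channel-transposed kernel). Max-pool ties route the gradient to
the first window position. All randomness (init, batch order,
augmentation) derives from one seed, so runs are exactly reproducible on
a given machine.

**Augmentation.** Once per case per epoch, one geometric transform is
sampled — scale uniform in [0.5, 1.5] about the image center, independent
per-axis translation uniform in ±10% of the image size, horizontal flip
with probability 0.5 — and applied identically to all input channels
(bilinear) and the mask (nearest, re-binarized), keeping the canvas size
fixed with zero fill. Translation "by 10%" is read as a uniform draw in
[−10%, +10%] per axis; per-image (not per-batch) sampling is assumed.
Training defaults: 40 epochs (desk scale; 500 at full scale),
mini-batch 5, Adam at 1e-3.

## Evaluation protocol

Pixel confusion counts against the ground-truth mask give accuracy,
recall, precision and F1. Ratios with zero denominator (no predicted or
no true positives) are recorded as undefined and excluded from averages,
with the exclusion count logged — synthetic edge cases must not crash the
harness. The binarization threshold for metrics is 0.5 (configurable).

Because the cohort is small, there is no held-out test set: validation is
leave-one-out cross-validation (fold i trains on the other n−1 cases and
validates on case i), and per-fold performance is the mean of each metric
over the final 10% of epochs — at 500 epochs this is the 450–500 window;
shorter schedules keep the same converged-tail fraction. Separately, the
ROC AUC (midrank Mann–Whitney formulation over the validation case's
pixels) is read at the epoch with the smallest *validation* loss
(earliest epoch on ties), probing attainable performance rather than
end-of-schedule performance.

Training is stochastic, so the whole LOOCV is repeated `n_experiments`
times (3 at desk scale, 11 at full scale); experiment e uses seed
`base_seed + e`, and each fold derives its own seed from (experiment
seed, fold index). Both arms see identical folds, seeds, batch orders and
augmentation draws — they differ only in input channels.

Two aggregation orders exist because per-experiment summaries can be
formed either by averaging per-case metrics (`case_mean`, default — it
matches the per-case LOOCV structure) or by pooling confusion counts over
all validation pixels first (`pixel_pooled`). AUC is always computed per
case and averaged.

Statistics follow the two natural pairings: Welch's unequal-variance
t-test (Welch–Satterthwaite df) compares arms across experiment repeats;
Wilcoxon's signed-rank test (zero differences dropped, midranks, exact
null for n ≤ 25 without ties, otherwise normal approximation with
continuity correction; W is the smaller rank sum) compares arms across
cases after averaging over experiments. Significance is two-sided at
α = 0.05.

## Synthetic data

The generator renders the minimal scene that carries the clinical
confound, not a photorealistic cervix:

* elliptical cervix (pale pink, smooth texture) on dark background;
* central reddish os region (columnar epithelium — barely changes with
  acetic acid);
* *confusers*: near-white irregular patches identical in both images
  (originally-white squamous epithelium), placed anywhere in the cervix
  including near the os so position alone cannot identify them;
* *lesions*: irregular blobs near the os boundary (the squamous-columnar
  junction), pink in the before-image and blended toward near-white in
  the after-image by the `lesion_whitening` fraction (default 0.85, which
  makes lesion-after color overlap the confuser color);
* ground truth mask = the lesion blobs exactly; every case has ≥1 lesion
  (cases without lesions are not evaluable and mirror exclusions in
  practice), and the lesion fraction of the cervix is kept in a 5–30%
  band for trainability;
* a random projective perturbation (each corner displaced by up to 5% of
  the image size; the homography is fit exactly to the displaced
  corners), through whose inverse the before-image is rendered;
* eight exact landmark correspondences on the cervix boundary, the true
  3×3 matrix, and independent per-image Gaussian noise (σ = 0.01 of full
  scale ≈ 2.5 8-bit levels); optional saturated specular spots
  (off by default).

Blob shapes are ellipses whose radius is modulated by random low-order
angular harmonics — irregular but smooth, seeded. Case i of a dataset
uses seed `dataset_seed + i`; everything is bitwise reproducible.

The built-in oracle classifiers document why the design works: on a
noiseless, unperturbed pair, thresholding the per-pixel before/after
change reproduces the mask exactly (F1 = 1), while the best single-image
rule — thresholding whiteness of the after-image — necessarily fires on
every confuser pixel. The dual-input network has a signal the control
network provably lacks.

**What passing tests do not show.** The generator has no mosaic or
punctation vascular patterns, no iodine staining, no non-planar
deformation of the cervix, no exposure or white-balance drift between the
two photographs, and its confuser/lesion color overlap is stylized. A
directional win of the dual-input arm here demonstrates that the pipeline
extracts change information end-to-end; it does not quantify clinical
performance.

## Problem sizes and numerical choices

The desk-scale profile — 64×64 images, 30 cases, small encoder
(depth 3, base 3), 40 epochs, batch 5, 3 experiments — was sized so the
complete two-arm repeated-LOOCV comparison (180 training runs) completes
in roughly ten minutes on one CPU core. The full-scale profile (480×640
crops, VGG16-style encoder, 500 epochs, 11 experiments) is selectable via
`--full-scale` but needs GPU-class compute.

Numerical details worth knowing: homography denormalization can leave
|h33| tiny for near-affine maps, hence the Frobenius fallback; points
with |w| < 1e-12 in the perspective divide raise a degeneracy error
rather than returning garbage; warped integer images are rounded and
clipped back to their dtype; downscaling verifies the aspect ratio within
1% and uses anti-aliased resampling (nearest + re-binarization for
masks); the LOOCV fold seed is derived through `numpy.random.SeedSequence`
so fold streams are independent; and training-time maxpool/ReLU
nondifferentiabilities follow standard subgradient choices (first-max
routing), which finite-difference tests avoid by using tie-free inputs.

## Known limitations

* The numpy/numba engine is CPU-only and single-threaded; full-scale
  (VGG16, 480×640, 500 epochs) training is out of its practical reach.
* No pretrained encoder weights are available, so the `vgg16_style`
  encoder reproduces the layout, not ImageNet transfer learning.
* Correspondences must be supplied (or generated); automatic
  correspondence detection across the acetic-acid appearance change is
  explicitly out of scope, as is elastic (non-projective) registration,
  specular-reflection removal, and CIN grade classification.
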