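# Methods

## Scope and data model

The package implements a five-class single-cell smear classifier with a
spatial attention gate, together with the machinery a study of such a
classifier needs: a synthetic data generator with ground truth, a
deterministic training loop, interval-bearing evaluation statistics,
attention/Grad-CAM visualization, and two comparison architectures.
Images are RGB arrays in `[0, 255]`; feature maps are
`(batch, channels, rows, cols)` float arrays; class labels are the five
fusion-gene subtype names (PML-RARA, TTMV-RARA, NPM1-RARA, STAT5B-RARA,
NUP98-RARG).

## Synthetic smear generator

Each class is a `ClassSignature`: nucleus shape (round, bilobed,
lobulated), nucleus/cell area fraction, cytoplasm and nucleus hue,
cytoplasmic granularity (speckles per 1000 px² of cytoplasm) and an
Auer-rod count interval. One cell is rendered per image — an ellipse of
cytoplasm with the nucleus built from overlapping lobes, centred with
±5% jitter on a pale background (gray level 230, Gaussian σ 6) — because
the interpretability claims concern single-cell crops. Rods are thin
rotated rectangles (length 10–16% of the image side, width 2 px)
rejection-sampled to lie inside the cytoplasm, clear of the nucleus and
of each other; only the PML-RARA-like class requests them, mirroring
the diagnostic role of Auer rods.

All five hues sit in the narrow pink/blue-violet range of a
Wright–Giemsa stain. This is deliberate: real smear classes are not
color-coded, so the generator encodes class identity mainly in
morphology (area fraction 0.28–0.72, lobe structure, granularity
0.4–4.0, rods). Default class counts are 509/98/58/38/12, the study's
class imbalance.

Determinism: per-sample seeds derive from the master seed through
`numpy.random.SeedSequence(master_seed, spawn_key=(class_index,
sample_index))`, so any per-class subset regenerates bit-identically in
isolation. Default image size is 128×128; the training pipeline resizes
downstream.

`class_separability_check` is a sanity gate, not a classifier: a
leave-one-out nearest-centroid accuracy over cheap summary features
(color moments, dark-pixel fraction, a Laplacian roughness proxy for
granularity, nucleus lobe count and elongation from a fixed luminance
threshold). Identical signatures score near chance; the default
signatures at 50 images/class score ≥ 0.8, confirming the classes are
learnable before any CNN enters the picture.

What the generator does **not** emulate: staining variation between
laboratories, focus/illumination gradients, touching or overlapping
cells, red-cell background clutter, and inter-patient morphological
variance. Passing tests on this data therefore demonstrate pipeline
correctness and learnability, not clinical performance.

## Network and optimization

All layers are implemented in NumPy with explicit forward and backward
passes (convolution via im2col and BLAS matrix products; batch norm
with running statistics, ε = 1e-5, momentum 0.1; He-initialized
weights). Correctness of every backward pass is enforced by central
finite-difference tests at float64, including through the full model
(relative agreement 1e-3, per the gradient-sanity invariant).

Architecture defaults (the study describes the topology but no sizes):
stem 3→32 3×3 convolution, stride 2; one residual block per stage with
channels (32, 64, 128) and stride 2 at stages 2 and 3; attention kernel
1×1; global average pooling; single fully connected layer. The stride-2
stem keeps stage 1 — where the attention gate lives — at half input
resolution, which quarters the dominant compute cost and matches common
residual-network stem practice; for a 64×64 input the attention map is
32×32. The shortcut is additive, with a 1×1 projected + batch-normed
branch when shape changes: the source text's word "concatenate"
conflicts with its own identity-mapping rationale, and the additive
form is the one that admits identity mappings.

Training defaults: 30 epochs, batch 32, Adam (β₁ 0.9, β₂ 0.999,
ε 1e-8), base learning rate 1e-3 halved every 10 epochs
(`lr = base · 0.5^⌊epoch/period⌋`), stratified 50/50 split with the odd
sample going to the training side. Preprocessing: bilinear resize to
the configured input size, scale to [0,1], standardize with mean 0.5 /
std 0.5 per channel. One master seed drives weight initialization,
splitting and per-epoch shuffling, making `TrainHistory` bit-reproducible
on a single device; the loss aborts with a diagnostic if it goes
non-finite. Cross-entropy floors probabilities at 1e-12 so a degenerate
zero at the true class is finite.

## Evaluation statistics

Confidence intervals are Wilson score intervals with the exact normal
quantile (z = 1.959964 at 95%), clipped to [0, 1]. The Wilson form was
chosen because it reproduces, at three decimals, every interval printed
in the study's three results tables from their integer
successes/trials inputs (e.g. 25/27 → (0.766, 0.979); 5/5 →
(0.566, 1.000); 350/357 → (0.960, 0.990)) — Wald and Clopper–Pearson do
not — and these reproductions are frozen as golden tests. F1 is
reported as a point value only, matching the tables; a zero denominator
yields a flagged 0.0 metric rather than an error, the convention the
weakest comparison model's table requires. Report values are rounded
half-up to 3 decimals.

ROC curves are one-vs-rest on the softmax probability of each class,
with tied scores grouped into single operating points and the curve
anchored at (0,0); AUC is the trapezoidal area, which equals the
tie-corrected Mann–Whitney statistic (property-tested on random
instances). A class absent from the truth yields an undefined (None)
AUC rather than a fabricated number.

## Visualization

The stage-1 attention map is upsampled bilinearly (corner-aligned, so
values stay within the input range), min-max normalized for display —
a constant map maps to 0.5 by convention — and passed through a
piecewise-linear colormap anchored at blue (0), cyan (0.25), green
(0.5), yellow (0.75), red (1): warm colors mean high attention.
Composites use `(1−α)·image + α·heatmap` with α = 0.4 by default.
Grad-CAM at any tagged layer weights each channel of the activation by
the spatial mean of the raw class-score gradient and rectifies the
weighted sum; it defaults to the deepest convolutional stage.

## Comparison models

`SelfAttentionResNet` replaces the original comparison's
ImageNet-pretrained ResNet50 — pretrained weights are out of scope —
with a randomly initialized residual backbone of the same family as the
primary model, plus a residual QKV self-attention block (1×1
projections, key-dimension scaling, softmax over spatial positions)
inserted before the final residual stage; the stated insertion point
"before the final convolutional layer" is ambiguous for a small
backbone, and this placement keeps the attention at a tractable spatial
size. The block is an exact identity when its value projection is zero.
`MultiLayerCNN` stacks six conv+BN+ReLU layers without shortcuts with
one spatial attention gate mid-stack. The attention-instability metric
turns the qualitative claim that some models' regions of interest
drift during training into a number: the mean per-pixel absolute change
of the display-normalized map between consecutive epochs, averaged over
fixed probe images.

## Problem sizes used by the test suite

The end-to-end suite trains the default model for 30 epochs at 64×64 on
a reduced-scale version of the study imbalance — 200/98/58/38/12 images,
i.e. the majority class capped at 200 so the 50/50 split leaves test
counts 100/49/29/19/6 — and evaluates on the held-out half. CLI smoke
tests use 10 images per class at 32×32 with 2 epochs. The interval
golden tests and the score-test/Mann–Whitney oracle suites run in
seconds.

## Known limitations

* **Attention localization is trajectory-dependent on this synthetic
  data.** After training to perfect synthetic test accuracy, the mean
  normalized attention inside the ground-truth cell mask exceeds the
  outside mean on all images of some classes and almost none of others,
  and which classes invert varies with the training seed (measured
  fractions 0.66–0.98 across seeds; 0.72 at the default seed). The
  cause is structural: the single-channel sigmoid gate multiplies every
  channel identically, so any spatially varying map that correlates
  with class identity is as useful to the classifier as one that
  highlights the cell, and on a cleanly separable synthetic set with a
  uniform background nothing penalizes the "class-encoding" solution.
  Real smears, where backgrounds contain clutter that must be
  suppressed, plausibly push the gate toward genuine localization; the
  synthetic set cannot demonstrate that.
* The generator's classes are far easier than real cytomorphology;
  perfect test accuracy here says nothing about accuracy on patient
  data.
* Batch norm couples samples within a batch during training; training
  is reproducible for a fixed batch size but not invariant to it.
* No augmentation, oversampling or early stopping is implemented; the
  study lists these as future work for its rare classes.
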