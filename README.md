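# cytoattn

Spatial-attention CNN pipeline for classifying acute promyelocytic
leukemia (APL) fusion-gene subtypes from single-cell bone marrow smear
images, with statistically rigorous evaluation and pixel-level attention
visualization.

## The problem

Classical APL carries the PML-RARA fusion; rarer variant translocations
(TTMV-RARA, NPM1-RARA, STAT5B-RARA, NUP98-RARG) look morphologically
similar but respond very differently to all-trans retinoic acid, so
telling them apart early matters clinically. Genetic confirmation takes
one to two weeks; a morphology-based classifier can flag the likely
subtype from smear images immediately — provided its decisions are
interpretable. This package implements such a classifier for
researchers who want a fully reproducible, dependency-light reference:
the model, the training loop and every statistic are implemented in
NumPy with explicit forward and backward passes, so every number the
pipeline prints can be traced to code in this repository.

Real smear collections for the rare subtypes are largely private, so the
package ships a seeded synthetic generator of five visually separable
single-cell classes (nucleus shape, nucleus/cell area fraction,
granularity, Auer-rod-like inclusions) with pixel-level ground-truth
masks, letting every downstream stage be exercised and audited without
access to patient data.

## The model

The classifier is a small residual CNN with a spatial attention gate:

1. stem: 3×3 convolution (stride 2) + batch norm + ReLU;
2. three residual stages (two 3×3 conv+BN each, additive shortcut with
   1×1 projection on shape change), channels 32 → 64 → 128, stride 2 at
   stages 2 and 3;
3. after stage 1, a spatial attention module: a 1×1 convolution
   compresses the feature map X to a single channel M, a sigmoid maps it
   to the attention map A ∈ (0,1)^{H×W}, and every channel is rescaled
   elementwise, Y_{k,i,j} = X_{k,i,j} · A_{i,j};
4. global average pooling and a fully connected layer produce the
   five-class scores.

Training uses cross-entropy, Adam, and a step schedule that halves the
learning rate every 10 epochs, on a stratified 50/50 train/test split.
Every binomial proportion in the evaluation report (per-class precision
and recall, overall accuracy) carries a 95% Wilson score interval

  ( p̂ + z²/2n ± z·√(p̂(1−p̂)/n + z²/4n²) ) / (1 + z²/n),

and per-class one-vs-rest ROC curves with trapezoidal AUC are produced
from the softmax probabilities. The attention map A is upsampled,
min-max normalized, mapped through a blue→cyan→green→yellow→red
colormap and alpha-blended over the input for interpretation; Grad-CAM
is available for the two comparison models (a residual backbone with a
QKV self-attention block, and a plain multi-layer CNN with the same
convolutional attention gate).

## Worked example

```
cytoattn generate --out data --seed 0 --image-size 128 \
  --counts "PML-RARA=40,TTMV-RARA=30,NPM1-RARA=24,STAT5B-RARA=20,NUP98-RARG=12"
cytoattn train --data data --out run --seed 0
cytoattn evaluate --data data --manifest run/test_manifest.csv \
  --checkpoint run/checkpoint.npz --out eval
cytoattn visualize --data data --manifest run/test_manifest.csv \
  --checkpoint run/checkpoint.npz --out viz --seed 1
```

`generate` writes 126 PNG images in five class directories with parallel
mask images and a `manifest.csv` (path, label, seed). `train` splits the
manifest 50/50 per class, trains 30 epochs at 64×64 and reports a
history; on this run the mean training loss fell from 1.442 (epoch 0) to
0.007 (epoch 29) while the learning rate stepped 0.001 → 0.0005 →
0.00025. `evaluate` prints

```
overall accuracy 1.0000 (95% CI 0.943, 1.000)
```

and writes `report.json` with per-class rows such as

```
PML-RARA    P=1.000 (0.839, 1.000)  R=1.000 (0.839, 1.000)  F1=1.000
NUP98-RARG  P=1.000 (0.610, 1.000)  R=1.000 (0.610, 1.000)  F1=1.000
```

— note how the Wilson interval widens as the per-class test count
shrinks (20 images for PML-RARA, 6 for NUP98-RARG) even though both
point estimates are 1.0: with few trials, a perfect score is weak
evidence. All five one-vs-rest AUCs are 1.0 on this easy synthetic set.
`visualize` writes a three-row panel (original / attention heatmap /
overlay) for one seeded random test image per class, and
`cytoattn compare` trains the two comparison models alongside the
primary one and tabulates accuracy, per-class F1 and an
attention-instability score (mean per-pixel change of the normalized
map between consecutive epochs on fixed probe images).

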