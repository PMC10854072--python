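# Methods

## The model

`mducnn` implements a U-shaped encoder–decoder for binary semantic
segmentation of biomedical images, in two spatial ranks (2D images, 3D
multi-channel volumes), built from two primitives:

**Multi-dimensional block.** Instead of the classical pair of 3×3
convolutions per stage, each stage chains three size-preserving 3×3
convolutions with progressively wider filter counts n₁ ≤ n₂ ≤ n₃ and
concatenates their three outputs along channels. Because the receptive
field grows with each chained 3×3 (3×3, 5×5, 7×7 effective), the
concatenation mixes multiple scales at the cost of a single 3×3 chain. A
1×1 convolution projects the block input to n₁+n₂+n₃ channels and is added
to the concatenation (a residual shortcut), followed by batch
normalization and ReLU. Every convolution is batch-normalized and
ReLU-activated; the network output is a 1×1 convolution with a sigmoid.

**Residual skip paths.** Plain U-Net skips concatenate shallow encoder
features with deep decoder features — semantically mismatched tensors.
Here each skip is a chain of residual units (3×3 convolution plus a
parallel 1×1 shortcut, added, then batch-norm/ReLU) of one shared width.
Shallower levels get more units (4, 3, 2, 1 at depth 4), since their
features are farthest from the decoder's.

**Filter schedule.** Level ℓ's width budget is M = β·Fₗ with β = 1.56 and
Fₗ the matched U-Net stage width (32, 64, …, doubling per level); M is
split ⌊M/6⌋, ⌊M/3⌋, ⌊M/2⌋ across the three convolutions. Two modes exist:

- `formula`: triples derived from β and `base_filters` as above (floor
  rounding by default — the bracket notation of the rule suggests it).
- `table_literal` (default for the five-level 2D model): the published
  five-level schedule verbatim — triples (7,18,26), (18,36,54),
  (36,73,107), (72,144,216), (146,292,428). No single β/rounding
  combination regenerates these printed counts exactly, so they are stored
  as data. The published 1×1 widths (52, 106, 214, 428, 856) differ
  slightly from the triple sums (51, 108, 216, 432, 866); a residual
  addition is only well-typed when the 1×1 width equals the concatenation
  width, so the sums are normative and the printed values are retained as
  `printed_res1` metadata.

**Decoder upsampling.** The decoder upsamples with a kernel-2/stride-2
transposed convolution whose output width equals the skip connection's
width at the target level, so each decoder stage concatenates two equally
wide tensors (e.g. 256+256=512 at the deepest skip of the 2D model). The
alternative of upsampling to the level's full schedule sum is available
(`up_channels="schedule"`) but rejected as a default: it makes the 2D
model heavier (8,480,819 trainable parameters) than the matched baseline
U-Net (7,781,617), defeating the architecture's stated goal of staying
below the U-Net budget. Under the default the 2D model has 7,420,894
trainable parameters.

**Baseline U-Net.** The comparison model is a classical U-Net with stage
widths [16, 32, 64, 128, 256, 512] (five poolings, pairs of 3×3
convolutions, transposed-conv upsampling that halves channels, plain skip
concatenation). Its 3D variant reduces depth by one and doubles filters
before pooling. The 3D multi-dimensional model likewise reduces depth by
one (three poolings, formula-mode schedule over base filters
[32, 64, 128, 256], four input channels).

**Ablation variants.** One generic skeleton exposes stage type
(multi-dimensional vs. double-conv) and skip type (residual path vs.
plain) independently, yielding the four-variant ablation matrix: baseline,
paths-only, blocks-only, full model.

## Objective, metric, protocol

Training minimizes pixelwise binary cross-entropy. The literal objective
is the per-image pixel *sum*; the default training reduction is the
per-pixel *mean* (identical optimum, scale-stable across image sizes; the
sum is available and equals mean × pixel count exactly). The batch loss is
the arithmetic mean of per-image losses. Optimization is adaptive-moment
gradient descent with first/second-moment decay rates α₁ = 0.9,
α₂ = 0.999 and learning rate 10⁻³ (the decay-rate description in the
protocol identifies the optimizer as Adam even where it is called
"stochastic gradient descent"; no values are published, so the field
defaults are used).

Evaluation is the Jaccard index |X∩Y|/|X∪Y| of the predicted and true
foreground pixel sets after thresholding at 0.5; ties at exactly 0.5 go to
foreground, and the empty∪empty case is defined as 1.0 (never reached by
the generator, which guarantees non-empty masks). Test Jaccard is averaged
per image, then over images (not pooled over pixels).

Cross-validation shuffles once (seeded), slices contiguously into k
disjoint folds (remainder to the earliest folds), trains a freshly seeded
model per fold, and records the mean test Jaccard after every epoch. The
reported figure is the *best* test Jaccard across epochs — the protocol
under study. That protocol peeks at the test set; it is reproduced
faithfully and flagged in every report (`protocol="best_on_test"`).
Summaries report mean ± sample standard deviation (n−1; the estimator is
not published, so the unbiased one is used) and model pairs are compared
by the simple difference of mean percentages, which reproduces four of the
five published comparison rows exactly (the MRI row prints 1.3241 where
the printed means differ by 1.9841; the discrepancy is recorded, not
resolved).

Augmentation multiplies the training set by exactly a factor of 3
(configurable): every original plus factor−1 seeded random
flip/right-angle-rotation combinations, applied identically to image and
mask. Right angles keep masks exact; arbitrary-angle rotation is
deliberately excluded from the default.

## The numpy engine

The networks run on a compact reverse-mode automatic-differentiation
engine written on numpy (`mducnn.nn`): channels-last tensors, im2col/GEMM
convolution (kernel 1 or 3 per axis, size-preserving), non-overlapping
kernel-2/stride-2 transposed convolution and max-pooling, batch
normalization (momentum 0.9, ε = 10⁻⁵, biased batch variance for the
running statistics), ReLU/sigmoid, channel concatenation, residual
addition, and a clamped (ε = 10⁻⁷) binary cross-entropy reduction. The
input gradient of a convolution is computed as a correlation with the
spatially flipped, channel-transposed kernel — a second GEMM rather than a
scatter. Every op's analytic gradient is tested against central finite
differences. Weights are initialized uniformly in
±√(6/fan_in) from a single per-model seed, so builds are bitwise
reproducible; inference is deterministic.

## Synthetic data

The generator emulates the *difficulty*, not the anatomy, of five
modalities; its defaults are the study conditions and are not tuned per
experiment. Foreground objects are wobbly ellipses (ellipsoids in 3D):
the ellipse radius is modulated by a 3-term cosine series in polar angle
(amplitudes ≤ 0.12). The binary mask is the exact pre-blur geometry; blur
and noise are applied to the image only, and the mask can be re-derived
bit-for-bit from the stored object parameters.

| preset | objects | radius (frac of extent) | contrast | blur σ (px) | noise sd | character |
|---|---|---|---|---|---|---|
| fluorescence | 3–8 | 0.06–0.14 | 0.70 | 0 | 0.03 | bright nuclei, 8 debris distractors excluded from the mask |
| endoscopy | 1–2 | 0.18–0.32 | 0.10 | 2.5 | 0.04 | the hard preset: low contrast, blurred boundary, textured bg |
| dermoscopy | 1 | 0.20–0.35 | 0.30 | 1.0 | 0.05 | strongly textured background |
| electron | 8–14 | 0.12–0.28 | 0.25 | 0.5 | 0.05 | union fills most of the frame (over-segmentation pressure) |
| mri3d | 1–2 | 0.15–0.30 | per channel 0.35/0.65/0.25/0.50 | 1.0 | 0.04 | 4 channels, one shared lesion geometry |

What passing tests on these data do **not** show: robustness to real
acquisition physics (specular highlights, hair, staining variability,
anisotropic voxels, partial-volume effects), to annotation noise (the
synthetic ground truth is exact), or to the scale of real training runs.
They do show that the architectures are correctly constructed, train
end-to-end, and that the full protocol (folds, tracking, reporting) is
implemented as specified.

## Desk-scale problem sizes

All training in the tests and the acceptance script is sized for a single
CPU: the cross-validation check uses a width-reduced formula-mode model
(base filters [8, 16, 32, 64], depth 3) on 120 easy-preset 64×64 images,
5 folds × 15 epochs at batch size 8; the memorization check uses a
depth-2 model (base filters [8, 16, 32]) on one 32×32 sample for 200
steps. These sizes are the package's chosen desk-scale study conditions;
full-scale absolute Jaccard values on the real benchmark datasets are out
of scope (external data, GPU-scale training), so the published parameter
totals enter only as upper bounds on the built models.

## Numerical and design choices

- Conv → batch-norm → ReLU ordering; the block's residual addition gets
  its own batch-norm + ReLU (the terminal stage of the block is otherwise
  unspecified; add-then-normalize is adopted).
- The three chained convolutions are each batch-normalized before
  concatenation, consistent with "every convolution batch-normalized".
- Batch norm stays on by default in 3D but is toggleable.
- Mask resizing: bilinear interpolation then re-binarization at 0.5.
- 2D intensities are divided by 255; 3D volumes are min–max scaled per
  volume and channel (only the 2D rule is published).
- Fold remainders go to the earliest folds; k defaults to 5
  (leave-one-out is k = n).
- Batch size defaults: 8 (2D), 2 (3D) — unpublished, chosen for one-CPU
  memory.
- Encoder and decoder blocks at the same level share one schedule entry
  (the five-level schedule's paired encoder/decoder blocks are read
  as one level).

## Known limitations

- CPU-only; wall-clock is dominated by GEMMs in float32. Full-resolution
  3D inference (80×80×48×4) takes ~25 s per volume.
- Binary segmentation only (single sigmoid channel); no multi-class head.
- The engine implements exactly the op set these architectures need; it is
  not a general DL framework (no dilation, no strides other than the fixed
  2× resampling, no GPU).
- Best-on-test reporting is an optimistic protocol; honest held-out
  evaluation requires an additional validation split, which the harness
  supports by passing separate test samples.
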