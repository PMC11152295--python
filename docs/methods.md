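# Methods

## Problem and scope

The package targets three-way staging of age-related macular degeneration
from grayscale OCT B-scans: *normal*, *drusen* (dry-AMD deposits
elevating the retinal pigment epithelium) and *CNV* (wet-AMD
neovascular lesions with sub-retinal fluid). It implements (i) the micro
and tiny variants of a hybrid convolution/transformer backbone family,
(ii) an architecture search that *stitches* a smaller pre-trained anchor
to a larger one through learned 1×1 linear maps, and (iii) the training
and cross-validation protocol used to score the resulting candidate
networks. Real clinical datasets are deliberately optional: a synthetic
B-scan generator provides label-faithful, separable images so the entire
pipeline is testable offline.

## Backbone model

Input images are resized to a square side (224 px by default), unit
scaled, normalized with a per-dataset mean/std (presets: 0.13/0.194 and
0.19/0.215) and replicated to 3 channels. The network is:

* **Stem** — four 3×3 conv+BN+ReLU layers (64, 32, 64, 64 channels;
  strides 2, 1, 1, 2), total spatial stride 4.
* **Stages 1–4** — each begins with a patch embedding (stride-2 average
  pool, except stage 1, then 1×1 conv+BN to the stage width: 96, 192,
  384, 768) followed by block groups:
  stage 1 `[ECB⁹⁶×3]`, stage 2 `[ECB¹⁹²×3 LTB²⁵⁶]`,
  stage 3 `[ECB³⁸⁴×4 LTB⁵¹²]×1` (micro) or `×2` (tiny),
  stage 4 `[ECB⁷⁶⁸×2 LTB¹⁰²⁴]`. With 224×224 input the stage spatial
  sides are 56/28/14/7.
* **Head** — global average pool → LayerNorm → linear classifier
  (3 classes throughout).

**ECB** = pre-norm residual MHCA, then pre-norm residual LFFN.
**LTB** = pre-norm residual ESA, then MHCA, then LFFN.
**MHCA** splits channels into heads of width `head_dim` (32 at full
scale); each head aggregates every position with its 3×3 neighbourhood
through learnable weights (realized as a grouped 3×3 convolution,
BN+ReLU), and a 1×1 convolution mixes the concatenated heads. **ESA** is
standard multi-head scaled dot-product attention with queries from all
tokens and keys/values from an average-pooled copy of the map
(per-stage strides 8/4/2/1, so pooling with stride 1 *is* plain
self-attention — asserted against a brute-force oracle). **LFFN** is
1×1 expand → 3×3 depthwise → ReLU → 1×1 project. The first block of a
group whose input width differs from its output carries a 1×1+BN
channel adaptation. Path dropout (stochastic depth on every residual
branch; 0.05 micro, 0.1 tiny) is the only stochastic layer.

### Block-internal conventions and the parameter calibration

The stage table fixes channels, strides, kinds and repeats but not the
block internals. The package fixes: BatchNorm everywhere on feature
maps, ReLU activations, qkv biases on, biased output projections, and
exposes the feed-forward expansion ratios and head width in
`BlockConventions`. The two expansion ratios were **calibrated once**,
by solving the analytic parameter-count equations, so that the fully
built 3-class micro and tiny networks land exactly on their published
sizes: `ecb_expansion = 3.0` (the conventional value for this block
family) and `ltb_expansion = 0.284375` (a bottleneck feed-forward in
the transformer blocks — the calibrated value implied by the published
totals given the other conventions). This yields 24,495,629 (24.50M)
and 31,141,203 (31.14M) trainable scalars; their difference is exactly
the analytic count of one extra stage-3 group. Both counts and the
difference identity are asserted in the test suite.

Residual-branch output projections are zero-initialized, so every block
starts as an identity plus a trainable perturbation. This is standard
practice in deep residual vision models and is what makes very short
training schedules (the desk-scale benchmarks below) converge; it does
not change parameter counts.

## Numerical engine

No GPU framework is used: `octstitch.nn` is a compact reverse-mode
autograd over float32 numpy arrays, with grouped/strided 2-d
convolution (sliding-window views + einsum), non-overlapping average
pooling, batch/layer norm, softmax attention, focal loss primitives,
AdamW and step/cosine schedules. Gradients are verified against central
finite differences; convolution against a naive loop; attention against
a dense float64 reference. Least-squares stitch solves use float64
`lstsq` (minimum-norm solution with a warning when the activation
matrix is rank-deficient, e.g. when the initialization batch has fewer
spatial tokens than stitch channels).

## Stitching search

Anchors must share input geometry; candidates pair only blocks in the
same pyramid stage because a 1×1 stitch cannot change spatial
resolution. Equal-depth stages use the sliding-window (paired)
enumeration, (n, n+1) for n = 1..L−1; a deeper back stage uses
proportional buckets: back position j belongs to front block
⌊(j−1)·L_A/L_B⌋+1, giving candidate (n, j+1) while j+1 ≤ L_B. Micro →
tiny yields stage-wise raw counts (2, 3, 9, 2); pruning drops odd
original indexes and re-indexes survivors from 0 (both indexings are
written to the space manifest). Stitches carry a bias, initialized from
the affine least-squares fit on a 100-sample batch of raw block-output
activations. During space training one candidate is drawn uniformly per
step and all parameters on its path update (a `freeze_anchors` mode
restricts updates to the stitches); the stitching learning rate scales
linearly with batch size relative to a reference batch of 32 and is
cosine-annealed to zero.

**Batch-norm recalibration.** The anchors' BN running statistics are
shared by every candidate although the stitched input distributions
differ; without correction, deep-suffix candidates evaluate near the
majority-class rate despite good ranking (high AUC). Before a candidate
is scored, its statistics are re-estimated by forwarding a few batches
through exactly that path with norm layers in batch mode and stochastic
depth off (`StitchingSpace.recalibrate_bn`, exact running average over
8 batches). This is the standard remedy for weight-sharing one-shot
search spaces and is applied by the five-fold driver and the sklearn
estimator.

## Training and evaluation protocol

Pre-training (`pretrain`): stratified 80/20 split with a fixed seed;
focal loss −α_y(1−p_y)^γ log p_y with γ = 2 and inverse-class-frequency
α (normalized to mean 1) by default — γ = 0 with uniform α reduces
exactly to cross-entropy; AdamW (lr 5e-5, step ×0.1 at epoch 50, batch
32, 75 epochs at full scale); per-epoch validation macro one-vs-rest
AUC with checkpointing on `auc >= best` so ties favour the later epoch.
Augmentation (training split only): random affine (rotation ±20°,
translation ±0.05/±0.2 of width/height, shear ±10°, scale 0.8–1.2),
then brightness/contrast/saturation jitter (0.8–1.2; saturation is the
identity on replicated grayscale), then horizontal flip (p = 0.5), then
normalization.

Metrics are macro (unweighted per-class, one-vs-rest): sensitivity =
mean TP/(TP+FN), specificity = mean TN/(TN+FP), AUC via scikit-learn's
macro OVR area; classes without true samples are excluded with a
warning. Cross-validated values are reported as mean ± 1.96·SD/√k
(normal approximation over the k = 5 fold values; a t-quantile option
exists). Folds are random at image level with a fixed seed, sizes
differing by ≤ 1; a patient-grouped splitter is provided since clinical
OCT archives are patient-structured. The five-fold driver has two
modes: out-of-distribution (anchors pre-trained once on the source
dataset; stitching trained per fold on 4/5 of the target) and
in-distribution (anchors re-pre-trained per fold on the remainder).
Zero-shot evaluation applies a trained checkpoint to a whole target
dataset with the target's normalization preset and no weight updates,
and refuses class-count mismatches.

## Synthetic data generator

Each image is a stack of 4 bright, gently curved horizontal bands
(quadratic baseline, randomized thickness/gaps/intensities) over a dark
background. *Drusen* adds 4–7 dome-shaped elevations of the lowest band
(Gaussian profiles in separate horizontal slots, with pixel floors so
domes stay resolvable at small renderings) with medium-reflectivity
deposit filling the vacated sub-band space. *CNV* adds one large
irregular bright lesion beneath the bands with a dark fluid pocket
nested against it. Multiplicative gamma speckle (mean 1, variance 0.02)
is applied last; pixels are clipped to [0, 1]. Class proportions default
to a normal-majority imbalance (0.55/0.25/0.20); pseudo-patient ids
group 8 consecutive same-class images for grouped splitting.

The generator's acceptance bar is a hand-coded detector independent of
any trained model (column-thickness excess for the lesion, deposit-band
area for drusen): ≥ 95% accuracy on 999 fresh images at the default
224 px — in practice ≈ 100%. What passing tests therefore show is that
the *machinery* (training, stitching, evaluation) works on cleanly
separable image classes; they say nothing about performance on real
scanner data, which has speckle-correlated texture, shadowing, vendor
post-processing and far subtler pathology.

## Desk-scale presets and problem sizes

Full-size training at 224 px is out of desk scope, so the test suite
and examples use `reduced` specs (all channels ÷ 8, inner repeats 1,
`head_dim` 4; the tiny variant keeps its doubled stage-3 group so the
two reduced anchors still exercise the unpaired strategy) on 32-px
synthetic images. The toy presets — `PretrainConfig.toy()` (5 epochs,
lr 7e-3, no augmentation) and `StitchTrainConfig.toy()` (200
iterations, lr 1e-3) — were chosen so that a freshly initialized
reduced network actually converges within the short schedule; the
Table-scale defaults (5e-5 etc.) remain the full-size values. The
benchmark run used throughout (600 images per dataset, five folds,
anchors pre-trained once) finishes in ~2.5 minutes on one CPU with
every stitched candidate above 0.90 held-out accuracy.

## Numerical choices and degenerate inputs

* float32 forward/backward; float64 for least squares and test oracles;
  comparisons at 1e-5 (attention equivalences), 1e-6 (identity
  recovery), 1e-7 (loss limits).
* ESA pooling requires the feature map divisible by the stride and
  falls back to identity otherwise (only reachable off the standard
  geometry); average pooling rejects indivisible shapes loudly.
* LFFN hidden widths round `dim × ratio` to the nearest integer.
* Apportionment of class counts uses largest-remainder rounding; ties
  in best-AUC checkpointing go to the later epoch; `AdamW` skips
  parameters without gradients, leaving off-path moments untouched.
* Rank-deficient stitch initialization warns and returns the
  minimum-norm solution.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; full-size (224 px)
  training is orders of magnitude slower than a GPU framework and only
  forward passes at that scale are exercised in tests.
* Printed parameter counts depend on the calibrated block conventions
  above; alternative internals (e.g. a different LTB feed-forward
  ratio) produce different totals by construction.
* The stitched-candidate indexing after pruning is one convention among
  several; the manifest records raw and pruned indexes so external
  numberings can be mapped.
* Only one-direction (smaller → larger), two-anchor stitching is
  implemented; distillation-based stitching and multi-anchor spaces are
  out of scope.
* The synthetic generator is geometric, not physical: no A-scan optics,
  shadowing, motion artifacts or vendor-specific contrast.
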