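# Methods

## Problem setting

Gallbladder lesions on B-mode ultrasound are classified into three groups —
normal, benign, malignant — under two practical constraints: expert
annotation is scarce, and speckle texture makes malignant masses (which often
lack clean margins) hard to characterise. The package implements a
three-phase pipeline that addresses both:

1. **Active sample selection** chooses which images deserve annotation,
   before any label exists.
2. **Self-supervised pretraining** learns a feature extractor from the
   selected images only, still without labels.
3. **Linear probing** freezes the extractor and fits a single affine
   classifier on the selected, now-annotated, embeddings.

Evaluation always happens on held-out *patients*: every patient's images sit
entirely on one side of any split.

## Phase 1 — variational-adversarial selection

A β-VAE encodes all images into a latent space; a three-layer MLP
discriminator is trained to distinguish latents of the already-selected pool
from the rest. The VAE objective is the sum over both pools of a Gaussian
reconstruction error (mean squared error, a Gaussian likelihood up to
constants) and β·KL(q(z|x) ‖ N(0, I)), plus an adversarial term that pushes
the discriminator toward labelling everything "selected":

    L_VAE = λ1·(recon + β·KL over both pools) + λ2·(−E log D(z_S) − E log D(z_U))
    L_D   = −E log D(z_S) − E log(1 − D(z_U))

Selection starts from a uniformly random 5% of the data and then, for each
budget in the schedule (default 15%/25%/35%), trains the minimax game and
acquires the unselected samples with the *lowest* discriminator score — the
ones least like anything already selected. Ties break by ascending index.
Acquisition scores use posterior means (not samples) so it is deterministic
given the trained weights. β = λ1 = λ2 = 1.

The algorithmic template also names a task learner updated alongside the
game; since this phase is label-free, no supervised objective exists for it,
and it is a deliberate no-op here.

Defaults: latent dimension 32, convolutional encoder/decoder working at
32 px, discriminator hidden width 64, Adam at 1e-3, float32 arithmetic.

## Phase 2 — the feature extractor and the MsHop block

The extractor is a residual convolutional network. Three profiles exist:
`micro` (stem + three residual stages of widths 16/32/32, all stride 2,
batch-normalised, ~50k parameters, 64 px input — the profile every test and
benchmark uses), and `resnet18` / `resnet50`-shaped profiles built from the
same blocks for larger experiments. Embeddings are produced by global
average pooling of *every* stage's output (a hypercolumn), concatenated and
mapped to `embed_dim` (default 32) by a linear head; pooling several depths
makes linear probes noticeably more stable at this scale than pooling the
last stage alone. ImageNet initialisation is refused at configuration time:
the package runs fully offline, so `pretrained_init` exists only to produce
a clear error.

**MsHop** (multi-scale high-order pooling) is inserted after stages 2 and 3
by default (mid-level features are where covariance statistics are most
informative; the insertion points are configurable). For input F of shape
H×W×D:

* *Hierarchical multi-scale stage.* F splits into four channel groups F_i;
  S_1 = K_1∗F_1 and S_i = K_i∗(F_i ⊕ S_{i−1}) for i = 2..4 with 3×3 kernels
  K_i and element-wise addition ⊕, so later groups see progressively larger
  receptive fields inside one block. The concatenation [S_1..S_4] is fused
  by a 1×1 convolution into F′.
* *Conditioning.* Before the second-order branch, F′ is standardised per
  sample and per channel over its spatial positions (no batch statistics
  enter the block). The cascaded convolutions otherwise amplify feature
  scale without bound, which saturates the attention sigmoids and lets the
  block's gradients dominate the global clipping budget — empirically the
  single largest source of failed training runs before this change.
* *Tri-directional covariance attention.* F′ is reduced along each axis —
  channels by a 1×1 convolution to D′, width and height by learned affine
  maps to W′ and H′ (a 1×1 convolution applied with that axis treated as the
  channel axis). For the channel branch every spatial position is one
  observation; for the width (height) branch every (height, channel)
  ((width, channel)) coordinate is one observation. Sample covariances are
  mean-centred with divisor m−1. Each covariance matrix feeds a gating
  head: a shared 1-D kernel convolved along every row (zero-padded 'same'),
  a mean over the row, an affine map from the matrix side-length back to the
  original axis length, and a sigmoid — producing λ_W ∈ (0,1)^W,
  λ_H ∈ (0,1)^H, λ_D ∈ (0,1)^D. The affine bridge is needed because a
  W′×W′ matrix must gate an axis of length W; a learned linear map is the
  minimal choice.
* *Fusion.* F̂ = Conv1×1(λ_W⊗F′ ⊕ λ_D⊗F′ ⊕ λ_H⊗F′) ⊕ F, each λ broadcasting
  along its own axis. The output 1×1 convolution is zero-initialised, so a
  freshly inserted block is an exact identity and cannot destabilise a
  pretrained or randomly initialised stage.

All MsHop statistics are per-sample; batch information never mixes inside
the block. Default reductions: W′ = ⌈W/2⌉, H′ = ⌈H/2⌉, D′ = ⌈D/4⌉ (the
construction only requires strict reduction); row-convolution kernel size 3.

## Phase 2 — the dual-branch objective

Two augmented views X_1, X_2 of each batch pass through the extractor
(Y_1, Y_2) and a three-layer expander with batch-normalised hidden layers
(Z_1, Z_2). Both views share one forward pass (and hence batch-norm
statistics).

**Contrastive branch** (variance-invariance-covariance family):

    L_con = λ·s(Z1,Z2) + μ·[v(Z1)+v(Z2)] + ν·[c(Z1)+c(Z2)]

with s the mean squared pair distance, v the hinge
(1/d)Σ_j max(0, γ − √(Var(z_j)+ϵ)) on column spread, and c the mean squared
off-diagonal of the d×d sample covariance. λ = μ = 25, ν = 1, γ = 1,
ϵ = 1e-4. The hinge uses the square root (standard-deviation) reading of
the regularised spread; the literal variance reading is available via
`sqrt_variance=False`.

**Clustering branch** (swapped prediction over learnable prototypes):
features and prototypes are unit-normalised; cosine scores are assigned to
codes Q on the transport polytope (rows 1/n, columns 1/K) by Sinkhorn-Knopp
with smoothing ε = 1e-4 and 3 iterations, finishing on the row
normalisation so row marginals are exact. The Sinkhorn iterations run in
log space: at ε = 1e-4 the assignments are near-hard and a probability-space
implementation underflows entire columns to zero. Codes are computed
without gradients; each view predicts the *other* view's codes through a
temperature-softmax (τ = 0.1) cross-entropy, with code rows rescaled to sum
to one so the loss is a per-sample average. K = 30 prototypes by default at
desk scale.

    L_total = L_con + α·L_clu,  α = 0.1

**Optimisation.** Adam (β1 = 0.9, β2 = 0.999), weight decay 1e-6, batch 64,
initial learning rate 0.003 with cosine decay over 800 steps — the reference
training recipe, and the package defaults. A 10-step linear warm-up and a global
gradient-norm ceiling of 10 guard the first iterations, where the
covariance penalty on a randomly initialised network is large. Training
runs in float32; the scalar arithmetic of the engine is float64 by default
elsewhere. After the last step, batch-norm running statistics are
re-estimated from one pass over the clean (unaugmented) selected images:
training batches are small and augmented, so the exponential estimates can
sit far from the statistics of the images the frozen model later embeds.

**Augmentation policy.** Random resized crop, horizontal flip (p = 0.5),
brightness/contrast jitter, Gaussian blur, and multiplicative speckle jitter
— all grayscale-safe and intensity-clamped. The generic defaults use crop
scale 0.6–1.0 and ±20% intensity jitter; the phantom *benchmark profile*
narrows these to crop 0.75–1.0 and ±8%/±10% jitter, because on the phantom
lesion brightness is a diagnostic cue and an invariance objective must not
be forced to discard it.

## Phase 3 — linear probe

Embeddings of the selected images are computed with the frozen extractor in
evaluation mode, standardised (training-set mean/scale — the composition is
still affine), and a single d→3 layer is fit by cross-entropy (Adam, 200
steps). At prediction time logits are averaged over the horizontal-flip
pair, a deterministic two-view ensemble that reduces variance at no
training cost.

## Synthetic phantom benchmark

The generator emulates the structure of a gallbladder B-mode dataset:
class proportions 0.344/0.445/0.211 and patient-level label homogeneity
mirroring the reference dataset's 432/558/265 images from 71/100/47
patients; 150 patients with 2–6 images each (~600 images) at 64 px. Anatomy
(lumen ellipse, wall thickness, lesion geometry) is drawn per patient;
per-image randomness is pose jitter and speckle. Rendering composes a
smooth tissue background, a dark lumen with an echogenic wall, class
findings — a bright sharply-marginated focus for benign; a darker,
heterogeneous, irregular-margin mass with a disrupted wall arc for
malignant — and multiplicative gamma speckle (scale 0.25), clamped to
[0, 1]. Margin irregularity is a random low-order Fourier modulation of the
mass radius.

What the phantom does *not* model: acoustic physics (attenuation, shadowing,
refraction), scanner/vendor variation, anatomical context beyond the
gallbladder, operator dependence, and the long tail of real lesion
morphology. Passing benchmarks on the phantom demonstrates that the
pipeline's machinery works end-to-end and that its components behave as
designed — not clinical performance.

The noise-robustness operator adds a zero-mean Gaussian field smoothed by a
spatial Gaussian kernel (σ = 5 px), rescaled after smoothing so its standard
deviation equals the level times the format dynamic range (1.0), then
clamps. "Level" is therefore a fraction of dynamic range and the field is
spatially correlated — the reading of a blur-kernel noise specification
that keeps the level interpretable.

## Desk-scale benchmark profile

All tests and the acceptance script run the `micro` profile: 64 px inputs,
batch 32, 160 optimiser steps, selection schedule 15/25/35%, VAE phase of 2
epochs per round, holdout fraction 0.25 by patient. One full pipeline run
takes under a minute on one CPU core. These sizes are the package's own
benchmark conditions; the reference-scale defaults (800 steps, batch 64)
remain the configuration defaults.

## Numerical choices

* Sample covariances everywhere use mean-centring and divisor m−1.
* Sinkhorn normalisation runs in log space with a global max-shift.
* Discriminator scores at exactly 0 are clipped at 1e-12 with a warning.
* Degenerate paired comparisons (zero-variance differences) report t = 0,
  p = 1 and a degeneracy flag rather than a numerical explosion.
* F1 is defined as 0 when precision + recall is 0, keeping macro-F1 defined
  on degenerate folds; 95% CIs use the normal approximation
  mean ± 1.96·sd/√k.
* Agreement (kappa) bounds treat the two raters' within-class joint
  correctness as free parameters constrained by Fréchet bounds; kappa is
  linear in those parameters, so the extremes are attained at box corners
  and the result is exact. Output is clamped to [−1, 1].
* Checkpoints are single-file `.npz` weight dictionaries with a YAML
  sidecar carrying a version tag, the configuration, and its hash.

## Known limitations

* The stochastic benchmark properties (label-efficiency parity, ablation
  deltas, noise monotonicity) carry real run-to-run variance at this scale;
  they are asserted on 5-seed means. Individual runs span roughly ±0.08
  accuracy around their mean.
* Self-supervised pretraining at a few hundred images occasionally converges
  to representations dominated by anatomy rather than lesion content; the
  hypercolumn pooling, warm-up, clipping and batch-norm recalibration
  reduce but do not eliminate this mode.
* The kappa-bound estimator assumes a shared prevalence and binary
  (malignant-vs-rest) margins; it does not attempt to reproduce any
  externally reported interval whose underlying assumptions (test-set size,
  class marginals) are unknown.
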