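# Methods

This note documents the models and procedures implemented in `histosynth`,
the parameters that matter, the numerical choices, and what the synthetic
test bed does and does not establish.

## Problem setting

Histopathology datasets large enough to train generative models are hard to
assemble, and expert segmentation masks are rarer still.  The pipeline here
targets that regime with two coupled ideas:

1. **Weak supervision by colour clustering.**  H&E staining maps tissue
   components to well-separated colours (hematoxylin-dark nuclei, eosin-pink
   cytoplasm, near-white background, erythrocyte-red vessel content), so a
   k-means clustering of pixel colours yields a serviceable surrogate
   ("clustering guide") for per-pixel class labels.
2. **Feature-conditioned progressive generation.**  A segmentation module
   trained on those pseudo-labels contains a reconstruction decoder whose
   intermediate feature grids summarise tissue layout at several scales.
   Concatenating those grids into the matching scales of a progressively
   grown GAN generator conditions synthesis on realistic tissue structure.

## Segmentation module

Two structurally symmetric U-shaped networks.  The segmentation network S
maps an RGB patch (network range [-1, 1]) to a K-channel softmax map; the
reconstruction network R maps the grey-scale mask image back to RGB through
a tanh head.  Both consist of four residual down-sampling blocks (RDB) and
four residual up-sampling blocks (RUB) with U-Net skip concatenations at
matching scales.

* RDB: sum of (two 3x3 depthwise-separable convolutions -> 2x average pool)
  and (1x1 convolution -> 2x average pool); halves H and W.
* RUB: sum of (2x nearest upsample -> two plain 3x3 convolutions) and
  (2x upsample -> 1x1 convolution); doubles H and W.
* LeakyReLU (slope 0.2) after every convolution; no normalisation layers.

The mask image is the argmax class scaled to [0, 1]: class k maps to
k/(K-1).  During joint training the reconstruction branch consumes the
*soft* mask (the per-pixel expected value of k/(K-1) under the softmax), so
that the reconstruction loss is differentiable through the segmentation
network; the hard mask is used for visualisation and feature extraction.
Joint training (rather than training S alone first) is what lets the
reconstruction objective sharpen the segmentation.

Losses: `L_total = CCE(S(x), c) + lambda_recon * MSE(R(m), x)` with the
k-means guide c and `lambda_recon = 5`.  CCE is the mean over pixels of
-ln p at the true class (natural log); MSE is the mean squared error in
network range.

Embedding features are tapped from the *reconstruction* network: the last
RDB output `F_enc` (input/16, 8x stem channels) and the first two RUB
outputs `F_dec1` (input/8, 4x stem) and `F_dec2` (input/4, 2x stem).  At
the default stem width of 64 and input 256 these are 16x16x512, 32x32x256
and 64x64x128.

## Clustering guide

Lloyd's algorithm with k-means++ initialisation (via scikit-learn) on a
pixel subsample pooled across the whole dataset (default 2,000 pixels per
patch), K = 4 by default.  A dataset-wide fit, rather than per-image fits,
makes class k mean the same tissue component in every guide mask — a
requirement for the cross-entropy target to be coherent across images.
Centroids are re-ordered canonically by ascending luminance
(0.299R + 0.587G + 0.114B, stable ties) so class identity survives refits.
Assignment is nearest-centroid in RGB with ties to the lowest class index.

## Generation module

A progressive GAN: stage resolutions 4, 8, ..., final (default 256).  The
initial block maps a 512-dimensional standard normal latent to a 4x4 grid
(dense layer + 3x3 convolution); each later stage is nearest upsample plus
two 3x3 convolutions; every stage has a 1x1-convolution + tanh to-RGB head.
New stages fade in linearly over the first half of the stage's steps:
output = (1-alpha) * upsample(previous RGB) + alpha * new RGB, which makes
growth exactly function-preserving at alpha = 0.

Conditioning: at stage resolutions 16 / 32 / 64 the feature grids F_enc /
F_dec1 / F_dec2 of a *frozen*, pre-trained reconstruction network (computed
from a reference patch drawn uniformly per batch) are concatenated
channel-wise to the stage input.  Feature grids whose native spatial size
differs from the stage resolution are average-pooled down, or
nearest-upsampled for aggressively scaled-down configurations, by the
power-of-two factor.  Features enter only the new branch during fade-in;
RGB-level blending provides continuity.  At sampling time the generator is
conditioned on features of caller-supplied reference patches, and each
sample's provenance (reference index, latent seed) is recorded.

The discriminator mirrors the generator (1x1 from-RGB, two 3x3 convs and a
2x average pool per stage, final 4x4 convolution + dense layer) and is an
unbounded Wasserstein critic; it never sees the embedding features.  Both
networks are built at full depth up front and grown by stage index, so
earlier-stage weights carry over between stages automatically.

Objective (WGAN-GP): critic loss `E[D(fake)] - E[D(real)] + gp` with
`gp = lambda_gp * E[(||grad_xhat D(xhat)||_2 - 1)^2]`,
`xhat = eps*real + (1-eps)*fake`, eps ~ U[0,1] per sample, lambda_gp = 10;
generator loss `-E[D(fake)]`.  One critic update per generator update by
default (configurable).  PGGAN's auxiliary stabilisers (pixel-norm,
equalised learning rate, minibatch stddev) are deliberately omitted: the
architecture is plain convolutions, LeakyReLU, progressive growth and
WGAN-GP.

## Parameters

| parameter | default | notes |
|---|---|---|
| K (classes) | 4 | 4-5 work for H&E component counts; fixed at 4 |
| lambda_recon | 5 | weight of the reconstruction MSE |
| lambda_gp | 10 | gradient-penalty coefficient |
| latent dim | 512 | standard normal |
| GAN optimiser | Adam, lr 1e-4, beta (0.9, 0.99) | both networks |
| seg optimiser | Adam, lr 1e-3, beta (0.9, 0.99) | see note below |
| LeakyReLU slope | 0.2 | all networks |
| fade-in | linear over first half of each stage | alpha=1 afterwards |
| tissue filter | luminance < 0.9 counts as tissue; keep if fraction >= 0.2 (inclusive) | prep stage |

Seg-module learning rate: at the desk scale this package trains at (64x64
patches, minutes of CPU), Adam at 1e-4 leaves the pseudo-label task visibly
under-fitted after a five-epoch budget (~86% pixel agreement with the
guides), while 1e-3 trains it comfortably (>=96%).  The generation module
keeps lr 1e-4.

## Numerical choices

* **Autodiff.**  All networks run on a small reverse-mode tensor autodiff
  engine over NumPy (`histosynth.nn`).  Every vector-Jacobian product is
  expressed in the engine's own primitives, so gradients are graph nodes
  and the second-order gradient needed to *train* the WGAN-GP penalty
  (differentiating through the critic's input gradient) works exactly.
  Convolutions are im2col + BLAS matmul; depthwise convolutions reuse
  im2col with a per-channel contraction.  float32 throughout.
* **Initialisation.**  He-normal, with each residual block's weights scaled
  by 1/sqrt(2): the two-path sum otherwise doubles activation variance per
  block, which across eight blocks saturates the tanh/softmax heads and
  stalls learning.  All initialisation derives from a single integer seed.
* **Gradient-penalty norm.**  ||g|| = sqrt(sum g^2 + 1e-16); the epsilon
  keeps the derivative finite for degenerate (constant) critics and
  perturbs the penalty by < 1e-6.
* **CCE stability.**  Training uses the log-softmax form; the public
  probability-map loss clamps p at 1e-12 (with a warning) if a true class
  has exactly zero probability.
* **FID.**  Population covariance (ddof = 0), so exact duplication of a set
  leaves the metric unchanged.  The matrix square root uses an
  eigendecomposition of the symmetrised product S_a^{1/2} S_b S_a^{1/2};
  eigenvalues below zero are clipped, with a warning beyond -1e-6.  The
  embedder is pluggable; the shipped ones (identity-flatten, seeded random
  projection) keep every code path testable offline, and an external
  feature network can be passed as a plain callable.
* **Mask degenerate case.**  K = 1 produces an all-zero mask (guarding the
  k/(K-1) division).
* **Tiling.**  0-based, row-major, half-open windows; partial windows at
  the right/bottom edges are dropped.  Filtering happens on the full-size
  window before the bilinear resize.
* **Determinism.**  Every stage's randomness derives from one global seed
  via a named hash (stage name + seed), so adding stages never perturbs
  existing streams.  Pipeline receipts store content hashes; checkpoint
  hashes are taken over parameter arrays rather than archive bytes (zip
  containers embed timestamps).

## Synthetic test bed

The fixture generator renders a stylised oligodendroglioma-like H&E patch:
pink cytoplasm matrix; dark-purple nuclear discs, each ringed by a
lightened-cytoplasm perinuclear halo (the "fried egg" look); optionally one
vessel (red wall, near-white lumen, the lumen coded as background); additive
Gaussian pixel noise (default sigma 0.02, small enough not to flip k-means
assignments for the default palette).  Nuclei are placed by rejection
sampling with at most 100 retries each; placements that fail are dropped
and reported.  Every patch carries an exact per-pixel component map
(recorded before noise) plus a halo mask; halo pixels are labelled
cytoplasm, since the halo is a cytoplasm-colour blend.  Default palette
colours are pairwise >= 0.2 apart in RGB, so K = 4 clustering is
well-posed.  Pseudo-whole-slides are tiled from patches with a near-white
background band making up 1 - tissue_fraction of the area.

What this fixture does *not* emulate: real stain variation between slides
and scanners, chromatin texture inside nuclei, tissue architecture
(chicken-wire capillaries, calcification), scanner artifacts, or multiple
magnifications.  Tests passing on it establish the correctness of the
mechanisms — exact pseudo-labels, loss analytics, shape contracts,
progressive continuity, training descent, metric closed forms — not
photorealistic synthesis quality on clinical data.

## Problem sizes used in the test suite

Training tests run at deliberately small scale so the whole suite completes
on one CPU in minutes: the segmentation-recovery check trains a 16-stem
module on 200 noiseless 64x64 patches for 5 epochs; the GAN smoke check
runs 500 steps per stage up to 32x32 over 256 patches with narrow channel
widths; the determinism audit runs the full pipeline twice at 8x8 final
resolution.  The architecture defaults (stem 64, final resolution 256,
channel plan 512...32) reproduce the printed feature shapes and are
exercised by shape-contract tests without full-scale training.

## Known limitations

* The engine is CPU-bound NumPy; full-scale (256x256, 120k-sample) training
  is out of its intended range — the package demonstrates and tests the
  method, it is not a GPU trainer.
* The generator is reference-conditioned by construction; sampling without
  any reference patch is undefined and rejected with an explanatory error.
* Stain-colour normalisation is explicitly out of scope.
* k-means pseudo-labels inherit colour ambiguity: components that share a
  colour (e.g. halo vs background whitening) can exchange labels; the
  canonical luminance ordering fixes identity but not assignment errors.
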