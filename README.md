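# histosynth

Synthesis of H&E histopathology patch images with a segmentation-guided
progressive GAN — including weakly supervised training when no segmentation
masks exist, and offline FID / Inception-Score evaluation.

## Who this is for

Digital-pathology and ML researchers who need realistic tumour-patch
synthesis (e.g. for augmenting small or imbalanced datasets) but whose
training corpus, like most clinical H&E collections, has **no per-pixel
annotations**.  The package implements the full workflow end to end and, in
place of clinical data, ships a synthetic H&E-like fixture generator with
exact ground truth, so every mechanism is testable on one CPU.

## The method

1. **Clustering guide.**  Per-pixel pseudo-labels come from k-means over
   RGB pixel colours pooled across the dataset (K = 4): H&E maps nuclei,
   cytoplasm, background and vessel content to well-separated colours.
   Centroids are ordered by luminance so class identity is stable.
2. **Segmentation module.**  Two symmetric U-shaped networks built from
   residual down-/up-sampling blocks (RDB/RUB): a segmentation network
   S: x → softmax mask and a reconstruction network R: mask → x̂ (tanh).
   Joint objective

   L_total = CCE(S(x), c) + λ_recon · MSE(R(S(x)), x),  λ_recon = 5,

   where c is the k-means guide.  The grey-scale mask is argmax class
   k ↦ k/(K−1).
3. **Generation module.**  A progressive GAN grown 4→256 px, trained with
   WGAN-GP (λ_gp = 10, Adam lr 1e-4, β = (0.9, 0.99)).  The generator is
   conditioned by channel-wise concatenation of the frozen reconstruction
   network's embedding features — F_enc (16×16×512), F_dec1 (32×32×256),
   F_dec2 (64×64×128) — at the matching generator scales:

   Img_G = G(z, F_enc, F_dec),  z ∼ N(0, 1)⁵¹².

4. **Evaluation.**  FID (Gaussian moment matching in an embedding space;
   pluggable embedder) and Inception Score (exp of the mean KL between
   per-image class posteriors and their marginal).

The networks run on a small NumPy reverse-mode autodiff engine
(`histosynth.nn`) with support for the double backprop that training the
WGAN-GP penalty requires.

## Worked example

```python
import numpy as np
from histosynth.synthetic import PatchSpec, generate_patches
from histosynth.clustering import fit_pixel_clusters, assign_guide, match_classes
from histosynth.segmodule import SegModuleConfig, train_seg_module

# 200 synthetic noiseless 64x64 H&E-like patches with ground truth
spec = PatchSpec(noise_sigma=0.0)
patches, cmaps = generate_patches(200, spec, seed=100)

# k-means pseudo-labels, checked against the known component maps
guide = fit_pixel_clusters(patches, k=4, seed=1)
guides = [assign_guide(p, guide) for p in patches]
pred = np.concatenate([g[~c.halo] for g, c in zip(guides[:50], cmaps[:50])])
true = np.concatenate([c.grid[~c.halo] for c in cmaps[:50]])
acc, _ = match_classes(pred[:, None], true[:, None], 4)
print(f"pseudo-label accuracy (non-halo): {100*acc:.1f}%")

# joint segmentation + reconstruction training
cfg = SegModuleConfig(input_size=64, stem_channels=16)
module, hist = train_seg_module(patches, guides, cfg, epochs=5, batch_size=8, seed=42)
print(f"L_total epoch 1: {hist[0]['l_total']:.3f} -> epoch 5: {hist[-1]['l_total']:.3f}")
seg_acc = np.mean([(module.segment(p).argmax(-1) == g).mean()
                   for p, g in zip(patches[:40], guides[:40])])
print(f"segmentation accuracy vs guides: {100*seg_acc:.1f}%")
```

Output:

```
pseudo-label accuracy (non-halo): 100.0%
L_total epoch 1: 1.550 -> epoch 5: 0.185
segmentation accuracy vs guides: 97.9%
```

The pseudo-labels recover the true tissue components exactly off the halo
rings (whose colour is a blend by construction); five epochs of joint
training drive the total loss down ~8x and the network reproduces its
guides on ~98% of pixels.

The same workflow is scriptable from the shell:

```bash
histosynth run-all --config my_run.yaml --seed 7
# stages: make-synthetic, prep, cluster, train-seg, train-gan, sample, evaluate
```

Each stage writes a receipt with content hashes; rerunning a completed
stage with unchanged inputs is a no-op, and two runs with the same seed
produce byte-identical artifacts.

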