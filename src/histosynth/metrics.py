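"""Generative-quality metrics: Fréchet distance (FID) and Inception Score.

Both metrics are defined against a pluggable embedder/classifier so the
formulas are testable without any pretrained network:

* **FID** fits a Gaussian (mean, population covariance) to the embeddings
  of each image set and evaluates the closed-form Fréchet distance
  ``||mu_a - mu_b||^2 + tr(S_a + S_b - 2 (S_a S_b)^{1/2})``.  The matrix
  square root uses an eigendecomposition of the symmetrised product
  ``S_a^{1/2} S_b S_a^{1/2}``, which is PSD up to round-off; small negative
  eigenvalues are clipped at zero (with a warning above 1e-6).
* **IS** is ``exp(E_x KL(p(y|x) || p(y)))`` computed per split, reported as
  mean +/- std across splits.

An embedder is any callable mapping an (N, H, W, C) image stack to (N, d)
vectors; :func:`identity_embedder` (flatten) and
:class:`RandomProjectionEmbedder` ship for offline use, and an external
feature network can be dropped in unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_NEG_EIG_WARN = 1e-6


@dataclass
class MomentSummary:
    """Gaussian moment summary of an embedded image set."""

    mean: np.ndarray          # (d,)
    cov: np.ndarray           # (d, d), symmetric PSD

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.cov = np.asarray(self.cov, dtype=np.float64)
        if self.mean.ndim != 1 or self.cov.shape != (self.mean.size,) * 2:
            raise ValueError("mean must be (d,), cov (d, d)")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @classmethod
    def from_embeddings(cls, emb: np.ndarray) -> "MomentSummary":
        emb = np.asarray(emb, dtype=np.float64)
        if emb.ndim != 2 or emb.shape[0] < 2:
            raise ValueError("need an (n >= 2, d) embedding matrix")
        mean = emb.mean(axis=0)
        centered = emb - mean
        cov = centered.T @ centered / emb.shape[0]   # population covariance
        return cls(mean, cov)


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    neg = vals.min()
    if neg < -_NEG_EIG_WARN:
        warnings.warn(f"clipping negative eigenvalue {neg:.3e} in matrix sqrt",
                      stacklevel=3)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(a: MomentSummary, b: MomentSummary) -> float:
    """Closed-form Fréchet distance between two Gaussian summaries."""
    if a.mean.size != b.mean.size:
        raise ValueError("dimension mismatch between summaries")
    diff = a.mean - b.mean
    sqrt_a = _psd_sqrt(a.cov)
    inner = _psd_sqrt(sqrt_a @ b.cov @ sqrt_a)   # = (S_a S_b)^{1/2} spectrum
    fd = float(diff @ diff + np.trace(a.cov) + np.trace(b.cov) - 2.0 * np.trace(inner))
    return max(fd, 0.0)


def identity_embedder(images: np.ndarray) -> np.ndarray:
    """Flatten each image to a vector — the trivial offline embedder."""
    images = np.asarray(images, dtype=np.float64)
    return images.reshape(images.shape[0], -1)


class RandomProjectionEmbedder:
    """Seeded Gaussian random projection of flattened images to ``dim``."""

    def __init__(self, input_size: int, dim: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dim = dim
        self._proj = rng.standard_normal((input_size, dim)) / np.sqrt(input_size)

    def __call__(self, images: np.ndarray) -> np.ndarray:
        flat = identity_embedder(images)
        if flat.shape[1] != self._proj.shape[0]:
            raise ValueError(
                f"embedder built for {self._proj.shape[0]} features, got {flat.shape[1]}")
        return flat @ self._proj


def fid(images_a: np.ndarray, images_b: np.ndarray, embedder=identity_embedder) -> float:
    """Fréchet distance between the embedded moments of two image sets."""
    emb_a = np.asarray(embedder(images_a))
    emb_b = np.asarray(embedder(images_b))
    if emb_a.shape[0] < 2 or emb_b.shape[0] < 2:
        raise ValueError("FID needs at least 2 images per set (covariance)")
    return frechet_distance(MomentSummary.from_embeddings(emb_a),
                            MomentSummary.from_embeddings(emb_b))


def inception_score(images: np.ndarray, classifier, n_splits: int = 10,
                    ) -> tuple[float, float]:
    """exp(mean KL(p(y|x) || marginal)) per split; returns (mean, std).

    ``classifier`` maps an image stack to an (N, K) row-stochastic matrix.
    """
    images = np.asarray(images)
    n = images.shape[0]
    if n < n_splits:
        raise ValueError("need at least one image per split")
    probs = np.asarray(classifier(images), dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] != n:
        raise ValueError("classifier must return an (N, K) probability matrix")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("classifier rows must sum to 1")
    scores = []
    bounds = np.linspace(0, n, n_splits + 1).astype(int)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        p = probs[lo:hi]
        marginal = p.mean(axis=0, keepdims=True)
        kl = (p * (np.log(np.clip(p, 1e-12, None))
                   - np.log(np.clip(marginal, 1e-12, None)))).sum(axis=1)
        scores.append(float(np.exp(kl.mean())))
    return float(np.mean(scores)), float(np.std(scores))


def score_report(metric: str, value: float, std: float | None, embedder: str,
                 n_a: int, n_b: int | None = None) -> dict:
    """Uniform JSON-ready record for emitted scores."""
    return {"metric": metric, "value": value, "std": std,
            "embedder": embedder, "n_a": n_a, "n_b": n_b}
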