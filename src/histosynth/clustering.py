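"""K-means colour clustering as a pseudo-label ("clustering guide") source.

When no expert segmentation masks exist, per-pixel class labels for H&E
patches can be manufactured by clustering pixel colours: hematoxylin-dark
nuclei, eosin-pink cytoplasm, vessel walls and near-white background fall
into well-separated RGB clusters, so nearest-centroid assignment yields a
serviceable surrogate mask.  The guide is fitted *once per dataset* on a
pooled pixel subsample so that class ``k`` denotes the same tissue
component in every mask, and centroids are canonically reordered by
ascending luminance so class identity is stable across refits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .prep import luminance


@dataclass
class ClusterGuide:
    """Fitted colour centroids in canonical (ascending-luminance) order."""

    centroids: np.ndarray                 # (K, 3) in [0, 1]
    k: int
    meta: dict = field(default_factory=dict)   # iterations, inertia, seed

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.shape != (self.k, 3):
            raise ValueError("centroids must be (K, 3)")

    def save(self, path: Path) -> None:
        with open(path, "w") as f:
            json.dump({"k": self.k, "centroids": self.centroids.tolist(),
                       "meta": self.meta}, f, indent=1)

    @classmethod
    def load(cls, path: Path) -> "ClusterGuide":
        with open(path) as f:
            d = json.load(f)
        return cls(np.asarray(d["centroids"]), d["k"], d.get("meta", {}))


def canonical_order(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort centroids by ascending luminance; stable on ties.

    Returns ``(sorted_centroids, permutation)`` with
    ``sorted_centroids[i] == centroids[permutation[i]]``.
    """
    centroids = np.asarray(centroids, dtype=np.float64)
    if centroids.size == 0:
        raise ValueError("no centroids to order")
    lum = luminance(centroids)
    perm = np.argsort(lum, kind="stable")
    return centroids[perm], perm


def _pool_pixels(patches: list[np.ndarray], sample_per_patch: int,
                 rng: np.random.Generator) -> np.ndarray:
    chunks = []
    for p in patches:
        flat = p.reshape(-1, 3)
        if sample_per_patch and flat.shape[0] > sample_per_patch:
            idx = rng.choice(flat.shape[0], size=sample_per_patch, replace=False)
            flat = flat[idx]
        chunks.append(flat)
    return np.concatenate(chunks, axis=0)


def fit_pixel_clusters(patches: list[np.ndarray], k: int = 4, seed: int = 0,
                       max_iter: int = 300, tol: float = 1e-6,
                       sample_per_patch: int = 2000) -> ClusterGuide:
    """Fit Lloyd's algorithm (k-means++ init) on pooled pixel colours.

    ``sample_per_patch`` pixels are drawn uniformly without replacement
    from each patch (0 means all pixels).  Raises if the pooled sample has
    fewer than ``k`` distinct colours.
    """
    if not patches:
        raise ValueError("no patches to fit on")
    rng = np.random.default_rng(seed)
    pixels = _pool_pixels(patches, sample_per_patch, rng)
    n_distinct = np.unique(pixels, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(
            f"need at least {k} distinct pixel colours, found {n_distinct}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                tol=tol, random_state=seed % (2 ** 32))
    km.fit(pixels)
    centroids, _ = canonical_order(km.cluster_centers_)
    return ClusterGuide(
        np.clip(centroids, 0.0, 1.0), k,
        meta={"iterations": int(km.n_iter_), "inertia": float(km.inertia_),
              "seed": int(seed), "n_pixels": int(pixels.shape[0]),
              "sample_per_patch": int(sample_per_patch)})


def assign_guide(patch: np.ndarray, guide: ClusterGuide) -> np.ndarray:
    """Nearest-centroid class map (H, W); ties go to the lowest class index.

    Distances are Euclidean in RGB.  ``np.argmin`` picks the first minimum,
    which implements the lowest-index tie-break.
    """
    flat = patch.reshape(-1, 3)
    d2 = ((flat[:, None, :] - guide.centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1).astype(np.uint8).reshape(patch.shape[:2])


def match_classes(pred: np.ndarray, truth: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    """Best-permutation pixel accuracy of ``pred`` against ``truth``.

    Solves the class-correspondence assignment exactly (Hungarian method on
    the confusion matrix) and returns ``(accuracy, mapping)`` where
    ``mapping[predicted_class] = truth_class``.
    """
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (pred.ravel(), truth.ravel()), 1)
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.zeros(k, dtype=np.int64)
    mapping[rows] = cols
    acc = conf[rows, cols].sum() / max(1, pred.size)
    return float(acc), mapping
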