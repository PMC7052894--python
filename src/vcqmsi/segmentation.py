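"""Automatic recognition of physiological regions.

Pixels are embedded with t-SNE on z-scored endogenous-metabolite profiles
and clustered with k-means, replacing manual ROI drawing on optical or H&E
images.  Agreement with a reference labeling is scored with the adjusted
Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score

from .msi_data import FeatureTable, LabelMap

__all__ = ["Embedding", "embed_pixels", "cluster_pixels", "label_agreement"]


@dataclass
class Embedding:
    coords: np.ndarray       # n_pixels x d
    pixel_index: np.ndarray  # row-aligned with coords
    grid_shape: tuple[int, int]
    perplexity: float
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")
        if self.coords.shape[0] != self.pixel_index.shape[0]:
            raise ValueError("coords not row-aligned with pixel_index")


def embed_pixels(features: FeatureTable, grid_shape: tuple[int, int],
                 d: int = 2, perplexity: float = 30.0, seed: int = 0,
                 ) -> Embedding:
    """t-SNE embedding of z-scored feature profiles; deterministic per seed."""
    n = features.n_pixels
    if n <= 3 * perplexity:
        raise ValueError(
            f"need more than {3 * perplexity:.0f} pixels for perplexity "
            f"{perplexity}, got {n}")
    X = features.matrix.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    tsne = TSNE(n_components=d, perplexity=perplexity, init="pca",
                random_state=seed)
    coords = tsne.fit_transform(Z)
    return Embedding(coords=np.asarray(coords, dtype=float),
                     pixel_index=features.pixel_index.copy(),
                     grid_shape=grid_shape, perplexity=perplexity, seed=seed)


def cluster_pixels(embedding: Embedding, k: int, seed: int = 0) -> LabelMap:
    """k-means (k-means++ init, 10 restarts, best inertia) on the embedding.

    Cluster ids are mapped back to the pixel grid as labels 1..k; pixels
    outside the embedding stay 0 (background).
    """
    n = embedding.coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds pixel count {n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    assign = km.fit_predict(embedding.coords)
    labels = np.zeros(embedding.grid_shape, dtype=int)
    labels[embedding.pixel_index[:, 0], embedding.pixel_index[:, 1]] = assign + 1
    names = {i: f"cluster_{i}" for i in range(1, k + 1)}
    return LabelMap(labels=labels, names=names)


def label_agreement(predicted: LabelMap, truth: LabelMap) -> float:
    """Adjusted Rand index over pixels labeled in both maps."""
    if predicted.shape != truth.shape:
        raise ValueError("label map shapes differ")
    both = (predicted.labels > 0) & (truth.labels > 0)
    if not both.any():
        raise ValueError("label maps have no co-occupied pixels")
    return float(adjusted_rand_score(truth.labels[both], predicted.labels[both]))
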