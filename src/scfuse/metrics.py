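"""Integration-quality metrics: batch mixing entropy and clustering agreement."""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError, ValidationError


def batch_mixing_entropy(
    latent: np.ndarray, batch, k_neighbors: int = 30
) -> float:
    """Average normalized Shannon entropy of batch labels in local neighborhoods.

    For each cell, the entropy of batch proportions among its ``k_neighbors``
    Euclidean nearest neighbors (self excluded), normalized by log(#batches)
    and averaged over cells.  1 means perfectly mixed batches, 0 means every
    neighborhood is single-batch.  Defined as 0 when only one batch exists.
    """
    latent = np.asarray(latent, dtype=np.float64)
    batch = np.asarray(batch, dtype=object).astype(str)
    if latent.shape[0] != len(batch):
        raise ValidationError("latent rows and batch labels must align")
    levels, codes = np.unique(batch, return_inverse=True)
    nb = len(levels)
    if nb < 2:
        return 0.0
    n = latent.shape[0]
    k = min(k_neighbors, n - 1)
    if k < 1:
        raise ParameterError("need at least 2 cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(latent)
    _, idx = nn.kneighbors(latent)
    ent = 0.0
    for i in range(n):
        neigh = idx[i][idx[i] != i][:k]
        counts = np.bincount(codes[neigh], minlength=nb)
        p = counts[counts > 0] / counts.sum()
        ent += float(-(p * np.log(p)).sum()) / np.log(nb)
    return ent / n


def clustering_ari(
    latent: np.ndarray, true_labels, n_clusters: int, seed: int = 0
) -> float:
    """Adjusted Rand index of seeded k-means against ground-truth labels."""
    latent = np.asarray(latent, dtype=np.float64)
    true_labels = np.asarray(true_labels, dtype=object).astype(str)
    if latent.shape[0] != len(true_labels):
        raise ValidationError("latent rows and labels must align")
    if n_clusters < 2:
        raise ParameterError("n_clusters must be >= 2")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    pred = km.fit_predict(latent)
    return float(adjusted_rand_score(true_labels, pred))
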