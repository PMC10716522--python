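"""Shared k-NN graph construction and seeded Leiden community detection."""

from __future__ import annotations

import warnings

import igraph
import leidenalg
import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["knn_edges", "leiden_cluster", "knn_leiden"]


def knn_edges(X: np.ndarray, k: int) -> np.ndarray:
    """Symmetric undirected edge list of the k-NN graph of row vectors."""
    n = X.shape[0]
    if n <= k:
        warnings.warn(f"n_samples={n} <= k={k}; reducing k to {n - 1}")
        k = max(n - 1, 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()
    edges = np.stack([np.minimum(src, dst), np.maximum(src, dst)], axis=1)
    return np.unique(edges[edges[:, 0] != edges[:, 1]], axis=0)


def leiden_cluster(
    n: int, edges: np.ndarray, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden partition (RB configuration model) of an undirected graph.

    Returns contiguous integer labels ordered by decreasing community size.
    """
    g = igraph.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # relabel so cluster 0 is the largest; deterministic tie-break by old id
    order = np.argsort([-np.sum(labels == c) * (n + 1) + c for c in range(labels.max() + 1)])
    remap = np.empty(labels.max() + 1, dtype=int)
    remap[order] = np.arange(order.size)
    return remap[labels]


def knn_leiden(X: np.ndarray, k: int = 15, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 1:
        return np.zeros(1, dtype=int)
    return leiden_cluster(X.shape[0], knn_edges(X, k), resolution, seed)
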