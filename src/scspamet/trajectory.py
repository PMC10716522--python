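"""Diffusion pseudotime and metabolite trends along declared branch paths.

Cells are ordered by diffusion distance from a root cell on the k-NN graph
of their (z-scored) protein features: a Gaussian kernel with adaptive
bandwidth (the distance to the k-th neighbour) gives a Markov transition
matrix whose nontrivial eigenvectors, scaled by lambda / (1 - lambda), span
the diffusion space; pseudotime is the Euclidean distance from the root in
that space, min-max normalised to [0, 1].  Branches are *declared* by the
user as ordered cluster paths (the bifurcation is read off the embedding,
not detected automatically), and the spatial direction of differentiation
is drawn as arrows from each cell to the mean centroid of its five nearest
neighbours in the next cluster on the path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors

from .io_formats import CellTable

__all__ = [
    "TrajectoryPath",
    "ArrowTable",
    "diffusion_pseudotime",
    "trend_along_pseudotime",
    "spatial_arrows",
]


@dataclass
class TrajectoryPath:
    """An ordered walk through cluster ids, e.g. dark zone -> light zone."""

    clusters: list
    root_cell: Optional[int] = None


def diffusion_pseudotime(
    table: CellTable,
    channels: Sequence[str],
    root_cell,
    k: int = 15,
    n_dcs: int = 10,
    seed: int = 0,
    precomputed: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pseudotime in [0, 1] per cell, 0 at the root.

    ``precomputed`` bypasses the internal computation (any externally
    computed pseudotime is accepted) and is only min-max normalised.
    """
    ids = table.df["cell_id"].to_numpy()
    root_pos = np.nonzero(ids == root_cell)[0]
    if root_pos.size == 0:
        raise ValueError(f"root cell {root_cell!r} not in table")
    root = int(root_pos[0])
    n = len(table)
    if precomputed is not None:
        pt = np.asarray(precomputed, dtype=float)
        if pt.shape[0] != n:
            raise ValueError("precomputed pseudotime length mismatch")
        lo, hi = pt.min(), pt.max()
        return (pt - lo) / (hi - lo) if hi > lo else np.zeros(n)

    X = table.channel_matrix(channels)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    sigma = dist[:, -1]
    sigma[sigma == 0] = np.min(sigma[sigma > 0]) if np.any(sigma > 0) else 1.0

    rows = np.repeat(np.arange(n), k_eff)
    cols = idx[:, 1:].ravel()
    d = dist[:, 1:].ravel()
    w = np.exp(-(d ** 2) / (sigma[rows] * sigma[cols]))
    W = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)  # symmetrize

    n_comp, _ = connected_components(W, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"k-NN graph has {n_comp} connected components; increase k or "
            "analyse components separately"
        )

    deg = np.asarray(W.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    S = W.multiply(d_inv_sqrt[:, None]).multiply(d_inv_sqrt[None, :])
    S = np.asarray(S.todense())
    S = 0.5 * (S + S.T)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the Markov matrix; drop the trivial stationary one
    psi = evecs * d_inv_sqrt[:, None]
    n_use = min(n_dcs, n - 1)
    lam = np.clip(evals[1 : n_use + 1], None, 1 - 1e-12)
    comps = psi[:, 1 : n_use + 1]
    # deterministic sign convention
    for j in range(comps.shape[1]):
        m = np.argmax(np.abs(comps[:, j]))
        if comps[m, j] < 0:
            comps[:, j] = -comps[:, j]
    comps = comps * (lam / (1 - lam))[None, :]
    pt = np.linalg.norm(comps - comps[root], axis=1)
    lo, hi = pt.min(), pt.max()
    return (pt - lo) / (hi - lo) if hi > lo else np.zeros(n)


def trend_along_pseudotime(
    pseudotime: np.ndarray,
    table: CellTable,
    channels: Sequence[str],
    n_bins: int = 50,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-channel mean in equal-count pseudotime bins, plus Spearman rho of
    each channel against pseudotime.  Constant channels get rho = NaN."""
    pt = np.asarray(pseudotime, dtype=float)
    if not np.isfinite(pt).all():
        raise ValueError("pseudotime must be finite")
    n = len(table)
    if n_bins > n:
        warnings.warn(f"n_bins={n_bins} > n_cells={n}; reducing")
        n_bins = n
    ranks = pd.Series(pt).rank(method="first").to_numpy() - 1
    bin_idx = np.floor(ranks * n_bins / n).astype(int)
    bin_idx = np.clip(bin_idx, 0, n_bins - 1)
    M = table.channel_matrix(channels)
    means = np.full((n_bins, M.shape[1]), np.nan)
    centers = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = bin_idx == b
        if sel.any():
            means[b] = M[sel].mean(axis=0)
            centers[b] = pt[sel].mean()
    trend = pd.DataFrame(means, columns=list(channels))
    trend.insert(0, "pseudotime", centers)
    rho = {}
    for c, name in enumerate(channels):
        x = M[:, c]
        if np.std(x) == 0 or np.std(pt) == 0:
            rho[name] = np.nan
        else:
            rho[name] = spearmanr(pt, x).statistic
    return trend, pd.Series(rho, name="spearman_rho")


@dataclass
class ArrowTable:
    """Spatial differentiation arrows: cell centroid -> mean centroid of its
    k nearest neighbours in the next cluster on the path."""

    df: pd.DataFrame  # cell_id, cluster, next_cluster, x0, y0, x1, y1


def spatial_arrows(
    table: CellTable,
    labels: np.ndarray,
    path: TrajectoryPath,
    k: int = 5,
) -> ArrowTable:
    labels = np.asarray(labels)
    if labels.shape[0] != len(table):
        raise ValueError("labels length does not match table")
    pts = table.centroids_um
    ids = table.df["cell_id"].to_numpy()
    rows = []
    for ck, cnext in zip(path.clusters[:-1], path.clusters[1:]):
        sel_k = np.nonzero(labels == ck)[0]
        sel_next = np.nonzero(labels == cnext)[0]
        if sel_k.size == 0 or sel_next.size == 0:
            raise ValueError(f"empty cluster on path: {ck!r} -> {cnext!r}")
        kk = min(k, sel_next.size)
        if kk < k:
            warnings.warn(f"cluster {cnext!r} has only {kk} cells; using k={kk}")
        tree = cKDTree(pts[sel_next])
        d, nb = tree.query(pts[sel_k], k=kk)
        nb = np.atleast_2d(nb.reshape(sel_k.size, kk))
        ends = pts[sel_next][nb].mean(axis=1)
        for i, ci in enumerate(sel_k):
            rows.append(
                {
                    "cell_id": ids[ci],
                    "cluster": ck,
                    "next_cluster": cnext,
                    "x0": pts[ci, 0],
                    "y0": pts[ci, 1],
                    "x1": ends[i, 0],
                    "y1": ends[i, 1],
                }
            )
    return ArrowTable(pd.DataFrame(rows))
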