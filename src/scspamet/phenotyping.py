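"""Pixel and single-cell phenotyping.

Pixel clustering follows a downsample-then-assign scheme: pixels from all
fields of view are pooled, a seeded 1/20 uniform subsample is standardised
and Leiden-clustered on its k-NN graph, and every remaining pixel takes the
majority label of its 30 nearest sampled pixels in feature space.

Cell masks come from nucleus label masks by 2-pixel nearest-label expansion
(cytosol = expanded minus nuclei); external whole-cell segmenters (Cellpose,
Mesmer) are an input, not implemented here — only the mask arithmetic is.
Per-cell features are per-channel mean intensities over the mask, plus
centroid (um) and area (px).  Cells are clustered with Leiden on z-scored
features (with an optional external batch-correction hook), and marker
gating fits a two-component 1-D Gaussian mixture with the threshold at the
posterior crossover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from skimage.segmentation import expand_labels
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from ._graph import knn_edges, leiden_cluster
from .io_formats import CellTable, LabelMask, MarkerImageStack

__all__ = [
    "PixelClusterModel",
    "GateResult",
    "cluster_pixels",
    "make_cell_masks",
    "cytosol_reference_images",
    "extract_cell_features",
    "cluster_cells",
    "gate_positive",
]


@dataclass
class PixelClusterModel:
    sampled_features: np.ndarray  # n_s x C standardized
    sampled_labels: np.ndarray
    sample_indices: np.ndarray  # positions of the sample in the pooled pixel list
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    kept_channels: np.ndarray  # indices of channels with sd > 0
    k_assign: int
    resolution: float
    seed: int

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Majority label among the k_assign nearest sampled pixels
        (ties break to the lowest label id)."""
        Xs = (X[:, self.kept_channels] - self.scaler_mean) / self.scaler_sd
        k = min(self.k_assign, len(self.sampled_features))
        nn = NearestNeighbors(n_neighbors=k).fit(self.sampled_features)
        _, idx = nn.kneighbors(Xs)
        votes = self.sampled_labels[idx]
        n_lab = self.sampled_labels.max() + 1
        out = np.empty(len(X), dtype=int)
        for i in range(len(X)):
            out[i] = np.bincount(votes[i], minlength=n_lab).argmax()
        return out


def cluster_pixels(
    stacks: Sequence,
    downsample: int = 20,
    k_graph: int = 15,
    k_assign: int = 30,
    resolution: float = 1.0,
    seed: int = 0,
) -> tuple[list, PixelClusterModel]:
    """Cluster pixels across fields of view; returns per-FOV label planes."""
    if not stacks:
        raise ValueError("need at least one stack")
    C = stacks[0].data.shape[0]
    for s in stacks:
        if s.data.shape[0] != C:
            raise ValueError("stacks must share a channel panel")
    X = np.concatenate([s.data.reshape(C, -1).T for s in stacks], axis=0)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    n_s = max(n // downsample, min(n, 2))
    sample_idx = np.sort(rng.choice(n, size=n_s, replace=False))

    sd = X[sample_idx].std(axis=0)
    kept = np.nonzero(sd > 0)[0]
    if kept.size < C:
        warnings.warn(f"dropping {C - kept.size} constant channel(s) from pixel clustering")
    if kept.size == 0:
        raise ValueError("all channels constant; nothing to cluster")
    mean = X[sample_idx][:, kept].mean(axis=0)
    sdk = sd[kept]
    Xs = (X[sample_idx][:, kept] - mean) / sdk

    labels_s = leiden_cluster(n_s, knn_edges(Xs, min(k_graph, n_s - 1)), resolution, seed)
    model = PixelClusterModel(
        sampled_features=Xs,
        sampled_labels=labels_s,
        sample_indices=sample_idx,
        scaler_mean=mean,
        scaler_sd=sdk,
        kept_channels=kept,
        k_assign=k_assign,
        resolution=resolution,
        seed=seed,
    )
    labels = np.empty(n, dtype=int)
    labels[sample_idx] = labels_s
    rest = np.setdiff1d(np.arange(n), sample_idx)
    if rest.size:
        labels[rest] = model.assign(X[rest])
    planes = []
    offset = 0
    for s in stacks:
        h, w = s.data.shape[1:]
        planes.append(labels[offset : offset + h * w].reshape(h, w))
        offset += h * w
    return planes, model


def make_cell_masks(
    nuclei: LabelMask,
    markers: Optional[MarkerImageStack] = None,
    cyto_markers: Optional[Sequence[str]] = None,
    mode: str = "expand2",
    expand_px: int = 2,
) -> tuple[LabelMask, LabelMask]:
    """Whole-cell and cytosol masks from nucleus labels.

    ``expand2``: every nucleus grows ``expand_px`` pixels by nearest-label
    expansion (collisions split at the Euclidean midline); cytosol is the
    expansion ring.  ``maxproj_minus_nuclei`` prepares inputs for an external
    whole-cell segmenter (see :func:`cytosol_reference_images`); without one
    attached it falls back to the expansion arithmetic.
    """
    if mode not in ("expand2", "maxproj_minus_nuclei"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "maxproj_minus_nuclei":
        if markers is None or cyto_markers is None:
            raise ValueError("maxproj mode needs a marker stack and cyto_markers")
        for c in cyto_markers:
            markers.panel.index_of(c)  # raises on unknown channel
        warnings.warn("no external segmenter attached; falling back to 2-px expansion")
    whole = expand_labels(nuclei.labels, distance=expand_px).astype(np.int32)
    cyto = np.where(nuclei.labels > 0, 0, whole).astype(np.int32)
    return (
        LabelMask(whole, nuclei.pixel_size_um),
        LabelMask(cyto, nuclei.pixel_size_um),
    )


def cytosol_reference_images(
    markers: MarkerImageStack, cyto_markers: Sequence[str], nuclei: LabelMask
) -> tuple[np.ndarray, np.ndarray]:
    """Max projection over cytosol markers, and the projection minus the
    nuclei foreground — the two images handed to a whole-cell segmenter."""
    planes = np.stack([markers.plane(c) for c in cyto_markers])
    proj = planes.max(axis=0)
    minus = np.where(nuclei.labels > 0, 0.0, proj)
    return proj, minus


def extract_cell_features(
    masks: LabelMask,
    stacks: Sequence,
) -> CellTable:
    """Per-cell mean intensity of every channel plus centroid (um) and area.

    All stacks must already be spatially aligned to the mask grid
    (post-registration).  Cells with zero pixels are excluded.
    """
    labels = masks.labels
    for s in stacks:
        if s.data.shape[1:] != labels.shape:
            raise ValueError(
                f"stack shape {s.data.shape[1:]} does not match mask {labels.shape}"
            )
    ids = masks.cell_ids
    if ids.size == 0:
        raise ValueError("mask contains no cells")
    area = ndimage.sum_labels(np.ones_like(labels), labels, ids)
    com = ndimage.center_of_mass(np.ones_like(labels, dtype=float), labels, ids)
    com = np.asarray(com).reshape(-1, 2)  # (row, col)
    ps = masks.pixel_size_um
    df = pd.DataFrame(
        {
            "cell_id": ids,
            "centroid_x_um": (com[:, 1] + 0.5) * ps,
            "centroid_y_um": (com[:, 0] + 0.5) * ps,
            "area_px": area.astype(int),
        }
    )
    for s in stacks:
        for j, name in enumerate(s.panel.names):
            df[name] = ndimage.mean(s.data[j], labels, ids)
    return CellTable(df)


def cluster_cells(
    table: CellTable,
    channels: Sequence[str],
    resolution: float = 1.0,
    seed: int = 0,
    k: int = 15,
    batch_key: Optional[str] = None,
    batch_hook: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Leiden clustering of z-scored per-cell features.

    ``batch_hook(X, batches) -> X_corrected`` is the external batch
    correction contract (same shape in and out); it is applied after the
    z-score when ``batch_key`` names a column.
    """
    X = table.channel_matrix(channels)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    if batch_key is not None and batch_hook is not None:
        batches = table.df[batch_key].to_numpy()
        Xc = batch_hook(X, batches)
        if np.shape(Xc) != X.shape:
            raise ValueError("batch hook changed the feature matrix shape")
        X = np.asarray(Xc, dtype=float)
    return leiden_cluster(len(table), knn_edges(X, k), resolution, seed)


@dataclass
class GateResult:
    threshold: float
    component_means: tuple[float, float]  # (mu_low, mu_high)
    positive: np.ndarray  # boolean per cell


def gate_positive(
    table: CellTable,
    channel: str,
    seed: int = 0,
    log_transform: bool = False,
) -> GateResult:
    """Gate cells positive for a marker whose intensity is bimodal Gaussian.

    Fits a 2-component 1-D Gaussian mixture (EM, seeded, 10 restarts); the
    threshold is the intensity where the component posteriors cross between
    the two means, and cells above it are positive.  Invariant to the
    mixture's component ordering.
    """
    if len(table) < 20:
        raise ValueError("need at least 20 cells to gate")
    x = table.channel_matrix([channel]).ravel()
    if log_transform:
        x = np.log1p(x)
    if np.std(x) == 0:
        raise ValueError("not bimodal: constant intensity")
    gm = GaussianMixture(
        n_components=2, n_init=10, random_state=seed, covariance_type="full"
    ).fit(x[:, None])
    if np.min(gm.weights_) < 1e-3:
        raise ValueError("not bimodal: degenerate mixture component")
    order = np.argsort(gm.means_.ravel())
    mu_low, mu_high = gm.means_.ravel()[order]
    if not mu_low < mu_high:
        raise ValueError("not bimodal: coincident component means")

    lo_c, hi_c = order[0], order[1]

    def post_diff(v: float) -> float:
        r = gm.predict_proba(np.array([[v]]))[0]
        return r[hi_c] - r[lo_c]

    a, b = float(mu_low), float(mu_high)
    if post_diff(a) < 0 < post_diff(b):
        threshold = float(brentq(post_diff, a, b))
    else:
        grid = np.linspace(a, b, 512)
        diffs = np.array([post_diff(v) for v in grid])
        threshold = float(grid[np.argmin(np.abs(diffs))])
    positive = x > threshold
    if log_transform:
        threshold = float(np.expm1(threshold))
        # positive mask already computed on the transformed scale
    return GateResult(threshold, (float(mu_low), float(mu_high)), positive)
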