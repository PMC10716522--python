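"""Spatial neighbour graphs and the local metabolite competition statistics.

The central quantity is the per-cell *competition ratio* m_i / agg(m_N(i)):
a cell's channel intensity divided by the aggregate (mean by default,
median optionally) intensity of its spatial neighbours.  A ratio of 1 means
parity with the neighbourhood; > 1 means the cell holds more of the
metabolite than its neighbours.  Neighbourhoods come either from a
centroid-radius graph (default 20 um, about one cell diameter) or from
mask-contact after binary dilation (for dense tissue).

Distance-to-vessel gradients: cells are assigned their 1-NN Euclidean
distance to a gated positive reference set (e.g. CD31+ endothelial cells),
channel means are computed in 20 equal-width distance bins and min-max
normalised to [0, 1] per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import pearsonr
from skimage.morphology import binary_dilation, disk

from ._graph import knn_edges, leiden_cluster
from .io_formats import CellTable, LabelMask

__all__ = [
    "SpatialGraph",
    "CompetitionTable",
    "GradientProfile",
    "build_graph",
    "competition_ratio",
    "distance_to_positive",
    "gradient_profile",
    "correlate_with_distance",
    "competition_vs_distance",
    "neighborhood_signature",
]


@dataclass
class SpatialGraph:
    """Symmetric cell neighbour graph without self-edges."""

    n_cells: int
    neighbors: list  # list of sorted int arrays, one per cell
    mode: str
    radius_um: Optional[float] = None

    def degree(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    def edges(self) -> np.ndarray:
        out = []
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                if j > i:
                    out.append((i, j))
        return np.array(out, dtype=int).reshape(-1, 2)


def _neighbors_from_pairs(n: int, pairs) -> list:
    nb = [[] for _ in range(n)]
    for i, j in pairs:
        if i == j:
            continue
        nb[i].append(j)
        nb[j].append(i)
    return [np.array(sorted(set(x)), dtype=int) for x in nb]


def build_graph(
    source,
    mode: str = "radius",
    radius_um: float = 20.0,
    dilation_px: int = 1,
) -> SpatialGraph:
    """Build the spatial neighbouring map.

    ``mode="radius"`` takes a :class:`CellTable` (or n x 2 centroid array in
    um) and connects centroids within ``radius_um`` of each other.
    ``mode="contact"`` takes a :class:`LabelMask`, dilates every cell mask by
    ``dilation_px`` and connects cells whose dilated masks overlap.
    """
    if mode == "radius":
        if isinstance(source, CellTable):
            pts = source.centroids_um
        else:
            pts = np.asarray(source, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2:
                raise ValueError("radius mode needs a CellTable or n x 2 centroids")
        tree = cKDTree(pts)
        pairs = tree.query_pairs(r=radius_um, output_type="ndarray")
        return SpatialGraph(len(pts), _neighbors_from_pairs(len(pts), pairs), mode, radius_um)

    if mode == "contact":
        if not isinstance(source, LabelMask):
            raise ValueError("contact mode needs a LabelMask")
        labels = source.labels
        ids = source.cell_ids
        id_to_idx = {int(l): i for i, l in enumerate(ids)}
        slices = ndimage.find_objects(labels)
        selem = disk(dilation_px)
        pad = dilation_px
        dilated = {}
        for lab in ids:
            sl = slices[lab - 1]
            r0 = max(sl[0].start - pad, 0)
            r1 = min(sl[0].stop + pad, labels.shape[0])
            c0 = max(sl[1].start - pad, 0)
            c1 = min(sl[1].stop + pad, labels.shape[1])
            crop = labels[r0:r1, c0:c1] == lab
            dilated[int(lab)] = ((r0, c0), binary_dilation(crop, selem))
        pairs = set()
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = int(ids[ai]), int(ids[bi])
                (ar, ac), am = dilated[a]
                (br, bc), bm = dilated[b]
                r0 = max(ar, br)
                c0 = max(ac, bc)
                r1 = min(ar + am.shape[0], br + bm.shape[0])
                c1 = min(ac + am.shape[1], bc + bm.shape[1])
                if r1 <= r0 or c1 <= c0:
                    continue
                a_sub = am[r0 - ar : r1 - ar, c0 - ac : c1 - ac]
                b_sub = bm[r0 - br : r1 - br, c0 - bc : c1 - bc]
                if np.any(a_sub & b_sub):
                    pairs.add((id_to_idx[a], id_to_idx[b]))
        return SpatialGraph(len(ids), _neighbors_from_pairs(len(ids), pairs), mode)

    raise ValueError(f"unknown graph mode {mode!r}")


@dataclass
class CompetitionTable:
    """Per-cell, per-channel competition ratios.

    ``ratios`` is an n_cells x n_channels DataFrame; NaN marks cells with no
    neighbours or a zero neighbour aggregate (never infinity).
    """

    ratios: pd.DataFrame
    aggregator: str
    n_neighbors: np.ndarray
    channels: list


def competition_ratio(
    table: CellTable,
    graph: SpatialGraph,
    channels: Sequence[str],
    aggregator: str = "mean",
) -> CompetitionTable:
    """ratio_{i,c} = m_{i,c} / agg_{j in N(i)} m_{j,c}.

    Multiplying any channel by a constant c > 0 leaves its ratios unchanged.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    if graph.n_cells != len(table):
        raise ValueError("graph and table disagree on cell count")
    M = table.channel_matrix(channels)
    agg_fn = np.mean if aggregator == "mean" else np.median
    out = np.full_like(M, np.nan, dtype=float)
    for i, nb in enumerate(graph.neighbors):
        if len(nb) == 0:
            continue
        denom = agg_fn(M[nb], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = M[i] / denom
        r[denom <= 0] = np.nan
        out[i] = r
    ratios = pd.DataFrame(out, columns=list(channels), index=table.df["cell_id"])
    return CompetitionTable(ratios, aggregator, graph.degree(), list(channels))


def distance_to_positive(
    table: CellTable,
    positive: np.ndarray,
    reference_table: Optional[CellTable] = None,
) -> np.ndarray:
    """1-NN Euclidean distance (um) of each cell to the positive reference set.

    ``positive`` is boolean over ``reference_table`` (default: ``table``
    itself, in which case positive cells get distance 0).  The reference may
    be a larger field than the query table, e.g. whole-core positives queried
    from a small FOV.
    """
    ref = reference_table if reference_table is not None else table
    positive = np.asarray(positive, dtype=bool)
    if positive.shape[0] != len(ref):
        raise ValueError("positive mask length does not match reference table")
    if not positive.any():
        raise ValueError("no positive cells in reference set")
    tree = cKDTree(ref.centroids_um[positive])
    d, _ = tree.query(table.centroids_um, k=1)
    return np.asarray(d, dtype=float)


@dataclass
class GradientProfile:
    """Binned distance-gradient profile of channel means."""

    bin_edges: np.ndarray  # n_bins + 1
    bin_means: pd.DataFrame  # n_bins x channels, NaN for empty bins
    normalized: pd.DataFrame  # min-max per channel over non-empty bins
    n_cells_per_bin: np.ndarray
    flat_channels: list


def _bin_index(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = 0.0, float(np.max(values))
    if hi <= lo:
        raise ValueError("all cells at a single distance; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(values, edges[1:-1]), 0, n_bins - 1)
    return idx, edges


def gradient_profile(
    distances: np.ndarray,
    table: CellTable,
    channels: Sequence[str],
    n_bins: int = 20,
) -> GradientProfile:
    """Equal-width distance bins over [0, max distance]; per-bin channel means,
    min-max normalised to [0, 1] per channel across the non-empty bins."""
    distances = np.asarray(distances, dtype=float)
    if len(distances) != len(table):
        raise ValueError("distances length does not match table")
    if len(table) < n_bins:
        warnings.warn(f"only {len(table)} cells for {n_bins} bins")
    idx, edges = _bin_index(distances, n_bins)
    M = table.channel_matrix(channels)
    means = np.full((n_bins, M.shape[1]), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = M[sel].mean(axis=0)
    norm = np.full_like(means, np.nan)
    flat = []
    occupied = counts > 0
    for c in range(M.shape[1]):
        col = means[occupied, c]
        lo, hi = np.min(col), np.max(col)
        if hi > lo:
            norm[occupied, c] = (means[occupied, c] - lo) / (hi - lo)
        else:
            norm[occupied, c] = 0.0
            flat.append(channels[c])
    cols = list(channels)
    return GradientProfile(
        edges,
        pd.DataFrame(means, columns=cols),
        pd.DataFrame(norm, columns=cols),
        counts,
        flat,
    )


def correlate_with_distance(
    distances: np.ndarray, table: CellTable, channels: Sequence[str]
) -> pd.Series:
    """Pearson r of each channel against distance; NaN on zero variance."""
    distances = np.asarray(distances, dtype=float)
    if len(table) < 3:
        raise ValueError("need at least 3 cells for a correlation")
    M = table.channel_matrix(channels)
    out = {}
    for c, name in enumerate(channels):
        x = M[:, c]
        ok = np.isfinite(x) & np.isfinite(distances)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(distances[ok]) == 0:
            out[name] = np.nan
        else:
            out[name] = pearsonr(distances[ok], x[ok]).statistic
    return pd.Series(out, name="pearson_r")


def competition_vs_distance(
    comp: CompetitionTable,
    distances: np.ndarray,
    cell_types: np.ndarray,
    type_a,
    type_b,
    n_bins: int = 20,
) -> dict:
    """Mean competition ratio per distance bin, separately for two cell types.

    Returns ``{type: DataFrame(n_bins x channels)}`` plus ``"bin_edges"``.
    """
    cell_types = np.asarray(cell_types)
    for t in (type_a, type_b):
        if not np.any(cell_types == t):
            raise ValueError(f"cell type {t!r} absent from table")
    distances = np.asarray(distances, dtype=float)
    idx, edges = _bin_index(distances, n_bins)
    R = comp.ratios.to_numpy()
    result = {"bin_edges": edges}
    for t in (type_a, type_b):
        sel_t = cell_types == t
        means = np.full((n_bins, R.shape[1]), np.nan)
        for b in range(n_bins):
            sel = sel_t & (idx == b)
            if sel.any():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    means[b] = np.nanmean(R[sel], axis=0)
        result[t] = pd.DataFrame(means, columns=comp.channels)
    return result


def neighborhood_signature(
    table: CellTable,
    labels: np.ndarray,
    radius_um: float = 25.0,
    resolution: float = 1.0,
    seed: int = 0,
    k_graph: int = 15,
    group_key: Optional[str] = None,
) -> tuple[np.ndarray, np.ndarray, Optional[pd.DataFrame]]:
    """Spatial joint-signature clustering from neighbourhood composition.

    For every cell, count the cluster labels among cells within ``radius_um``
    (the cell itself included, so isolated cells get a one-hot vector) and
    divide by the total so each composition vector sums to one.  The vectors
    are then clustered a second time with Leiden to give spatial signature
    labels; if ``group_key`` names a column (e.g. ``patient_id``), a
    signature-frequency table per group is returned as well.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    labels = np.asarray(labels)
    if labels.shape[0] != len(table):
        raise ValueError("labels length does not match table")
    uniq = np.unique(labels)
    lab_idx = np.searchsorted(uniq, labels)
    pts = table.centroids_um
    tree = cKDTree(pts)
    neighborhoods = tree.query_ball_point(pts, r=radius_um)
    sig = np.zeros((len(table), uniq.size))
    for i, nb in enumerate(neighborhoods):  # query_ball_point includes self
        counts = np.bincount(lab_idx[nb], minlength=uniq.size)
        sig[i] = counts / counts.sum()
    sig_labels = leiden_cluster(len(table), knn_edges(sig, min(k_graph, len(table) - 1)),
                                resolution, seed)
    freq = None
    if group_key is not None:
        freq = pd.crosstab(table.df[group_key], pd.Series(sig_labels, name="signature"),
                           normalize="index")
    return sig, sig_labels, freq
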