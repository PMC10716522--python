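"""Ground-truth tissue simulator for paired SIMS / IMC modality images.

The generator builds every structure the downstream statistics assume, so
the whole pipeline can be exercised end to end without deposited data:

* a hard-core point process of disk-shaped cells (radius ~5 um, matching a
  10 um mean cell diameter; minimum centre spacing 8 um) with concentric
  nuclei, a designated vessel (endothelial-like) cell type and >= 2 ordinary
  types;
* cell-type-specific protein profiles and metabolite channels composed of a
  baseline, additive type effects, exponential decay away from the nearest
  vessel cell (A * exp(-d / lambda)), planted monotone pseudotime trends and
  planted neighbourhood competition asymmetry (sink-type cells gain a factor
  g > 1, their graph neighbours are depleted by 1/g);
* paired images of the same tissue: the IMC stack covers the whole field at
  1 um pixels, the SIMS stack is a smaller, denser window related to it by a
  known affine misalignment, which is stored for registration tests.

Noise is multiplicative lognormal by default (unit mean, configurable
dispersion) so intensities stay positive, matching ion-count character;
zero dispersion reproduces the planted means exactly.  All generators are
pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import (
    CellTable,
    ChannelEntry,
    ChannelPanel,
    IonImageStack,
    LabelMask,
    MarkerImageStack,
)
from .registration import AffineTransform2D
from .spatial_analysis import build_graph

import pandas as pd

__all__ = [
    "GroundTruthTissue",
    "ExpressionModel",
    "RenderedPair",
    "simulate_tissue",
    "simulate_expression",
    "render_pair",
    "lung_like_model",
    "simulate_dataset",
]


@dataclass
class GroundTruthTissue:
    n_cells: int
    centers_um: np.ndarray  # n x 2, (x, y)
    cell_type: np.ndarray  # int per cell; type 0 is the vessel type
    nuclei_mask: LabelMask
    cell_mask: LabelMask
    pseudotime_true: np.ndarray  # float in [0, 1] per cell
    field_um: float
    pixel_size_um: float
    seed: int

    @property
    def vessel_cells(self) -> np.ndarray:
        return np.nonzero(self.cell_type == 0)[0]


def simulate_tissue(
    n_cells: int,
    field_um: float = 400.0,
    type_probs: Sequence[float] = (0.4, 0.35, 0.25),
    vessel_frac: float = 0.05,
    seed: int = 0,
    pixel_size_um: float = 1.0,
    min_spacing_um: float = 8.0,
    cell_radius_um: float = 5.0,
    nucleus_radius_um: float = 3.0,
) -> GroundTruthTissue:
    """Scatter disk cells by hard-core dart throwing and render label masks.

    ``type_probs`` are the frequencies of the ordinary (non-vessel) types,
    which get ids 1..T; a fraction ``vessel_frac`` of cells is the vessel
    type (id 0).  Deterministic given the seed; raises when the field cannot
    hold ``n_cells`` at the minimum spacing.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    type_probs = np.asarray(type_probs, dtype=float)
    if type_probs.size < 2 or abs(type_probs.sum() - 1.0) > 1e-8:
        raise ValueError("type_probs must be >= 2 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    margin = cell_radius_um
    lo, hi = margin, field_um - margin
    if hi <= lo:
        raise ValueError("field too small for the cell radius")
    centers = []
    tree_pts: list = []
    attempts = 0
    max_attempts = 2000 * n_cells
    while len(centers) < n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"field {field_um} um too small for {n_cells} cells at "
                f"{min_spacing_um} um spacing"
            )
        p = rng.uniform(lo, hi, size=2)
        if centers:
            d2 = np.sum((np.asarray(centers) - p) ** 2, axis=1)
            if d2.min() < min_spacing_um ** 2:
                continue
        centers.append(p)
    centers = np.asarray(centers)

    n_vessel = int(round(vessel_frac * n_cells)) if vessel_frac > 0 else 0
    if vessel_frac > 0:
        n_vessel = max(n_vessel, 1)
    cell_type = np.zeros(n_cells, dtype=int)
    ordinary = rng.choice(np.arange(1, type_probs.size + 1), size=n_cells, p=type_probs)
    cell_type[:] = ordinary
    vessel_idx = rng.choice(n_cells, size=n_vessel, replace=False)
    cell_type[vessel_idx] = 0

    # render disks: each pixel takes the label of the nearest centre in range
    npix = int(round(field_um / pixel_size_um))
    rr, cc = np.meshgrid(np.arange(npix), np.arange(npix), indexing="ij")
    px = (cc.ravel() + 0.5) * pixel_size_um
    py = (rr.ravel() + 0.5) * pixel_size_um
    tree = cKDTree(centers)
    d, idx = tree.query(np.column_stack([px, py]), k=1)
    cell_labels = np.where(d <= cell_radius_um, idx + 1, 0).reshape(npix, npix).astype(np.int32)
    nuc_labels = np.where(d <= nucleus_radius_um, idx + 1, 0).reshape(npix, npix).astype(np.int32)

    pseudotime_true = rng.uniform(0.0, 1.0, size=n_cells)
    return GroundTruthTissue(
        n_cells=n_cells,
        centers_um=centers,
        cell_type=cell_type,
        nuclei_mask=LabelMask(nuc_labels, pixel_size_um),
        cell_mask=LabelMask(cell_labels, pixel_size_um),
        pseudotime_true=pseudotime_true,
        field_um=field_um,
        pixel_size_um=pixel_size_um,
        seed=seed,
    )


@dataclass
class ExpressionModel:
    """Cell-type-specific expression program for both modalities.

    ``protein_means`` is T x P with row t the mean protein vector of type t
    (row 0 = vessel type).  Metabolite channel c of cell i has mean::

        baseline_c + type_effects[type_i, c]
        + A * exp(-d_i / lambda)        (gradient channels; d_i = distance
                                         to the nearest vessel cell, um)
        + slope * pseudotime_i          (pseudotime channels)

    then competition channels multiply sink-type cells by g and their
    non-sink graph neighbours (radius graph, 20 um) by 1/g, and finally
    multiplicative noise is applied.
    """

    protein_names: list
    metab_names: list
    protein_means: np.ndarray  # T x P
    metab_baseline: np.ndarray  # M
    type_effects: np.ndarray  # T x M
    gradient_channels: list = field(default_factory=list)  # (channel_name, lambda_um, amplitude)
    competition_channels: list = field(default_factory=list)  # (channel_name, sink_type, gain)
    pseudotime_channels: list = field(default_factory=list)  # (channel_name, slope)
    noise: str = "lognormal"
    dispersion: float = 0.2
    # "all": sinks gain g, every other cell is depleted by 1/g (the two-level
    # asymmetry the competition-vs-distance statistic asserts);
    # "neighbors": only graph neighbours of sinks are depleted
    competition_depletion: str = "all"

    def __post_init__(self) -> None:
        self.protein_means = np.asarray(self.protein_means, dtype=float)
        self.metab_baseline = np.asarray(self.metab_baseline, dtype=float)
        self.type_effects = np.asarray(self.type_effects, dtype=float)
        if np.any(self.protein_means <= 0) or np.any(self.metab_baseline <= 0):
            raise ValueError("all mean intensities must be > 0")
        for _, lam, _ in self.gradient_channels:
            if lam <= 0:
                raise ValueError("gradient decay length must be > 0")
        for _, _, g in self.competition_channels:
            if g <= 1:
                raise ValueError("competition sink gain must be > 1")
        if self.noise not in ("lognormal", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def n_types(self) -> int:
        return self.protein_means.shape[0]


def _apply_noise(mean: np.ndarray, model: ExpressionModel, rng: np.random.Generator) -> np.ndarray:
    if model.dispersion == 0:
        return mean.copy()
    if model.noise == "lognormal":
        s = model.dispersion
        return mean * rng.lognormal(mean=-0.5 * s ** 2, sigma=s, size=mean.shape)
    return rng.poisson(mean).astype(float)


def simulate_expression(
    tissue: GroundTruthTissue,
    model: ExpressionModel,
    seed: int = 0,
    competition_radius_um: float = 20.0,
) -> CellTable:
    """Draw the per-cell feature table implied by the expression program."""
    if model.n_types != tissue.cell_type.max() + 1 and model.n_types < tissue.cell_type.max() + 1:
        raise ValueError("expression model has fewer types than the tissue")
    rng = np.random.default_rng(seed)
    n = tissue.n_cells
    t = tissue.cell_type

    if model.gradient_channels and tissue.vessel_cells.size == 0:
        raise ValueError("gradient channels requested but tissue has no vessel cells")
    if tissue.vessel_cells.size:
        tree = cKDTree(tissue.centers_um[tissue.vessel_cells])
        d_vessel, _ = tree.query(tissue.centers_um, k=1)
    else:
        d_vessel = np.full(n, np.nan)

    metab_mean = model.metab_baseline[None, :] + model.type_effects[t]
    name_to_col = {nm: j for j, nm in enumerate(model.metab_names)}
    for ch, lam, amp in model.gradient_channels:
        metab_mean[:, name_to_col[ch]] += amp * np.exp(-d_vessel / lam)
    for ch, slope in model.pseudotime_channels:
        metab_mean[:, name_to_col[ch]] += slope * tissue.pseudotime_true
    if np.any(metab_mean <= 0):
        raise ValueError("metabolite means must stay positive; check slopes/effects")

    if model.competition_channels:
        graph = build_graph(tissue.centers_um, mode="radius", radius_um=competition_radius_um)
        for ch, sink_type, gain in model.competition_channels:
            col = name_to_col[ch]
            sinks = np.nonzero(t == sink_type)[0]
            if model.competition_depletion == "all":
                factor = np.full(n, 1.0 / gain)
            else:
                factor = np.ones(n)
                depleted = set()
                for s in sinks:
                    depleted.update(int(j) for j in graph.neighbors[s])
                depleted -= set(int(s) for s in sinks)
                if depleted:
                    factor[list(depleted)] = 1.0 / gain
            factor[sinks] = gain
            metab_mean[:, col] *= factor

    protein = _apply_noise(model.protein_means[t], model, rng)
    metab = _apply_noise(metab_mean, model, rng)

    areas = np.bincount(tissue.cell_mask.labels.ravel(), minlength=n + 1)[1:]
    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "centroid_x_um": tissue.centers_um[:, 0],
            "centroid_y_um": tissue.centers_um[:, 1],
            "area_px": areas,
            "cell_type": t,
            "pseudotime_true": tissue.pseudotime_true,
            "distance_to_vessel_um": d_vessel,
        }
    )
    for j, nm in enumerate(model.protein_names):
        df[nm] = protein[:, j]
    for j, nm in enumerate(model.metab_names):
        df[nm] = metab[:, j]
    return CellTable(df)


@dataclass
class RenderedPair:
    """A rendered IMC / SIMS pair with its ground-truth misalignment."""

    sims: IonImageStack
    imc: MarkerImageStack
    true_transform: AffineTransform2D  # moving (SIMS) px -> fixed (IMC) px


def _paint(mask: np.ndarray, values_by_label: np.ndarray) -> np.ndarray:
    """Paint per-cell values onto a label mask (label k -> values[k-1])."""
    lut = np.concatenate([[0.0], values_by_label])
    return lut[mask]


def render_pair(
    tissue: GroundTruthTissue,
    cells: CellTable,
    model: ExpressionModel,
    true_transform: Optional[AffineTransform2D] = None,
    sims_fov: Optional[tuple[int, int, int, int]] = None,
    noise_sigma: float = 0.02,
    seed: int = 0,
    upsample: int = 2,
) -> RenderedPair:
    """Render the paired modality images of one tissue.

    The IMC stack covers the full field (protein channels + a DNA channel
    over nuclei).  The SIMS stack covers ``sims_fov`` = (y0, x0, h, w) in
    IMC pixels, sampled at ``upsample`` x higher pixel density, after the
    window-local misalignment ``true_transform`` (IMC-pixel units, e.g. a
    rotation about the window centre plus a translation; identity when
    omitted).  The composed moving-to-fixed transform is returned so planted
    misalignments are recoverable by the registration stages.

    Additive Gaussian background noise (sd ``noise_sigma`` times the mean
    foreground level) corrupts both stacks; ion planes are clipped at zero.
    """
    rng = np.random.default_rng(seed)
    cm = tissue.cell_mask.labels
    nm = tissue.nuclei_mask.labels
    H, W = cm.shape
    if sims_fov is None:
        h = w = int(min(H, W) * 0.5)
        sims_fov = ((H - h) // 2, (W - w) // 2, h, w)
    y0, x0, fh, fw = sims_fov
    if true_transform is None:
        true_transform = AffineTransform2D.identity()

    # full transform: moving px -> fov-local IMC px -> misaligned -> IMC px
    up = AffineTransform2D(
        np.array([[1.0 / upsample, 0.0, 0.5 / upsample - 0.5],
                  [0.0, 1.0 / upsample, 0.5 / upsample - 0.5]])
    )
    full = AffineTransform2D.translation(x0, y0).compose(true_transform).compose(up)

    mh, mw = fh * upsample, fw * upsample
    corners = np.array([[0, 0], [mw - 1, 0], [0, mh - 1], [mw - 1, mh - 1]], dtype=float)
    mapped = full.apply(corners)
    if (mapped < -0.5).any() or (mapped[:, 0] > W - 0.5).any() or (mapped[:, 1] > H - 0.5).any():
        raise ValueError("SIMS field of view falls outside the IMC field after transform")

    P = len(model.protein_names)
    protein_vals = cells.channel_matrix(model.protein_names)
    imc_planes = [
        _paint(cm, protein_vals[:, j]) for j in range(P)
    ]
    dna_level = float(np.mean(protein_vals))
    imc_planes.append(_paint(nm, np.full(tissue.n_cells, dna_level)))
    imc = np.stack(imc_planes)
    imc += rng.normal(0.0, noise_sigma * max(dna_level, 1e-9), size=imc.shape)
    imc_entries = [
        ChannelEntry(j, nm, "protein") for j, nm in enumerate(model.protein_names)
    ] + [ChannelEntry(P, "DNA", "dna")]
    imc_panel = ChannelPanel(tuple(imc_entries))
    imc_stack = MarkerImageStack(np.clip(imc, 0, None), imc_panel, tissue.pixel_size_um)

    metab_vals = cells.channel_matrix(model.metab_names)
    truth_planes = [_paint(cm, metab_vals[:, j]) for j in range(len(model.metab_names))]
    po3_level = float(np.mean(metab_vals))
    truth_planes.append(_paint(nm, np.full(tissue.n_cells, po3_level)))
    # moving(x_m) = truth(full(x_m)): sample the fixed-frame truth at the
    # transformed coordinates
    sims_planes = [full.inverse().warp(p, (mh, mw)) for p in truth_planes]
    sims = np.stack(sims_planes)
    sims += rng.normal(0.0, noise_sigma * max(po3_level, 1e-9), size=sims.shape)
    sims = np.clip(sims, 0, None)
    sims_panel = ChannelPanel.from_names(
        list(model.metab_names) + ["PO3"],
        "metabolite",
        mz=list(np.arange(1, len(model.metab_names) + 1, dtype=float)) + [79.0],
    )
    sims_stack = IonImageStack(sims, sims_panel, tissue.pixel_size_um / upsample)
    return RenderedPair(sims_stack, imc_stack, full)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def lung_like_model(
    n_proteins: int = 12,
    n_metabolites: int = 24,
    n_types: int = 4,
    dispersion: float = 0.2,
    seed: int = 0,
) -> ExpressionModel:
    """A lung-tumour-like expression program.

    Type 0 is the CD31+ vessel type; types 1..3 stand in for tumour, T-cell
    and macrophage-like populations.  The first protein is the CD31 gate
    marker; each type over-expresses a small block of markers (mean 8 vs
    baseline 1).  Metabolite channels include one vessel-distance gradient
    channel, one tumour-sink competition channel and one pseudotime channel.
    """
    rng = np.random.default_rng(seed)
    protein_names = ["CD31", "PanCK", "CD3", "CD68"] + [
        f"marker_{i}" for i in range(n_proteins - 4)
    ]
    metab_names = [f"mz_{25 + 4 * i}" for i in range(n_metabolites)]
    protein_means = np.ones((n_types, n_proteins))
    for t in range(min(n_types, 4)):
        protein_means[t, t] = 8.0
    # secondary markers so types differ in > 1 coordinate
    for t in range(n_types):
        extra = 4 + (np.arange(2) + 2 * t) % max(n_proteins - 4, 1)
        protein_means[t, extra] = 4.0
    metab_baseline = np.full(n_metabolites, 5.0)
    # clearly type-dependent metabolite profiles (up to ~60 % of baseline),
    # the regime the joint embedding is meant to resolve
    type_effects = rng.uniform(0.0, 3.0, size=(n_types, n_metabolites))
    type_effects[:, :3] = 0.0  # keep the planted-effect channels clean
    return ExpressionModel(
        protein_names=protein_names,
        metab_names=metab_names,
        protein_means=protein_means,
        metab_baseline=metab_baseline,
        type_effects=type_effects,
        gradient_channels=[(metab_names[0], 60.0, 20.0)],
        competition_channels=[(metab_names[1], 1, 3.0)],
        pseudotime_channels=[(metab_names[2], 10.0)],
        noise="lognormal",
        dispersion=dispersion,
    )


def simulate_dataset(
    n_cells: int = 400,
    field_um: float = 400.0,
    seed: int = 0,
    dispersion: float = 0.2,
    vessel_frac: float = 0.05,
) -> tuple[GroundTruthTissue, ExpressionModel, CellTable]:
    """One-call tissue + expression draw with the lung-like preset."""
    tissue = simulate_tissue(
        n_cells, field_um=field_um, vessel_frac=vessel_frac, seed=seed
    )
    model = lung_like_model(dispersion=dispersion, seed=seed + 1)
    cells = simulate_expression(tissue, model, seed=seed + 2)
    return tissue, model, cells
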