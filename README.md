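# scspamet

Joint single-cell analysis of untargeted spatial metabolomics (TOF-SIMS) and
targeted multiplexed protein imaging (IMC) acquired sequentially from the
same tissue section.

TOF-SIMS images ~200 metabolite/lipid fragment ion channels (indexed by m/z)
at sub-micron pixels but carries no cell-type information; IMC images 20–40
metal-tagged protein markers at ~1 µm pixels and resolves cell types but no
metabolites. This package aligns the two modalities onto single cells and
implements the downstream statistics that such paired data enables: local
metabolite competition between neighbouring cells, metabolite gradients as a
function of distance to vessels, a joint protein–metabolite variational
embedding, spatial niche signatures, and metabolite trends along
differentiation pseudotime. Everything runs end to end on synthetic
paired-modality tissue, so the full pipeline is testable without any
deposited imaging data.

## The statistics at the core

**Mean ion-count normalisation.** Each SIMS pixel *i* with channel vector
X<sub>i</sub> ∈ ℝ<sup>p</sup> is rescaled by its mean intensity over all p
ion channels, Y<sub>i</sub> = X<sub>i</sub> · p / Σ<sub>j</sub> x<sub>ij</sub>,
so every non-empty pixel has channel mean 1.

**Three-stage registration.** The SIMS field of view is a small, possibly
rotated and sheared window inside the IMC field. Using one reference plane
per modality (nuclear marker vs. the 79 m/z phosphate ion), the pipeline
runs FFT template matching (translation), phase correlation of the angular
marginals of polar-resampled FFT magnitude spectra (rotation), and
difference-of-Gaussian keypoints + RANSAC (residual affine), composed into a
single 2×3 transform and scored by SSIM/NRMSE against random-shift and
rotation-only baselines.

**Competition ratio.** For cell *i* with neighbourhood N(i) (centroids
within 20 µm, or touching masks after dilation), the per-channel competition
ratio is m<sub>i</sub> / agg(m<sub>N(i)</sub>) — 1 at parity with the
neighbourhood, above 1 for cells holding more of a metabolite than their
neighbours.

**Distance gradients.** Cells positive for a marker (e.g. CD31) are gated by
a two-component Gaussian mixture; every cell gets its 1-NN distance to the
positive set, and channel means in 20 distance bins (min–max normalised per
channel) plus per-channel Pearson r quantify vessel-distance gradients.

**Joint VAE.** A dual-encoder variational autoencoder (protein: P→16→8;
metabolite: M→128→64→32→8; concatenated → dense 16 → µ, σ ∈ ℝ¹⁶) is trained
by minimising MSE<sub>p</sub> + MSE<sub>m</sub> + β·KL(N(µ,σ)‖N(0,I)) with
the reparameterisation z = µ + σ⊙ε. Latent means feed Leiden clustering and
25 µm neighbourhood-composition "spatial signature" clustering.

**Diffusion pseudotime.** Cells are ordered by diffusion distance from a
root cell on the k-NN graph of z-scored protein features; channel trends
along user-declared cluster paths are summarised by equal-count bin means
and Spearman ρ, with spatial 5-NN arrows showing the direction of
differentiation in the tissue.

## Worked example

```python
import numpy as np
from scspamet import registration as reg
from scspamet import spatial_analysis as sa
from scspamet import phenotyping as ph
from scspamet import synthetic_data as sd

# a 400-cell synthetic tissue and its paired, misaligned modality images
tissue, model, cells = sd.simulate_dataset(n_cells=400, field_um=420.0,
                                           seed=7, dispersion=0.2)
mis = reg.AffineTransform2D.translation(15.0, -8.0).compose(
    reg.AffineTransform2D.rotation(12.0, (84.5, 84.5)))
pair = sd.render_pair(tissue, cells, model, true_transform=mis,
                      sims_fov=(120, 100, 170, 170), noise_sigma=0.02,
                      seed=7, upsample=2)

res = reg.register(pair.imc, pair.sims)
print(f"registration: rotation {res.rotation_deg:+.2f} deg, "
      f"translation (dy, dx) = {res.translation_px}, "
      f"SSIM {res.ssim:.3f}, NRMSE {res.nrmse:.3f}")

gate = ph.gate_positive(cells, "CD31", seed=0)
d = sa.distance_to_positive(cells, gate.positive)
ch = model.gradient_channels[0][0]
r = sa.correlate_with_distance(d, cells, [ch])
print(f"Pearson r({ch}, distance to CD31+) = {r[ch]:.3f}")

graph = sa.build_graph(cells, mode="radius", radius_um=20.0)
comp = sa.competition_ratio(cells, graph, [model.competition_channels[0][0]])
```

Output:

```
registration: rotation +11.94 deg, translation (dy, dx) = (112, 115), SSIM 0.742, NRMSE 0.129
Pearson r(mz_25, distance to CD31+) = -0.780
```

The planted 12° rotation is recovered to 0.06°, and the SIMS window is
located at IMC pixel (112, 115) — the planted field-of-view origin
(120, 100) plus the planted translation, as expected. The planted
vessel-distance decay channel `mz_25` correlates negatively with distance to
the gated CD31+ cells (r = −0.78 at 20 % multiplicative noise; ≤ −0.9 at
zero noise). The competition table holds per-cell, per-channel ratios:
tumour-like sink cells sit above parity (median ≈ 2.5 for the planted
competition channel) while their depleted neighbours sit below it.

A thin CLI mirrors the main steps
(`scspamet simulate`, `convert`, `normalize`, `register`, `compete`,
`gradient`, `signatures`, `pseudotime`).

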