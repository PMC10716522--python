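# Methods

This note documents the models, parameter choices and numerical conventions
behind `scspamet`, and what the synthetic-data generator does and does not
emulate.

## Coordinate and data conventions

Images are `C x H x W` float64 arrays; pixel `(row r, col c)` has its centre
at `((c + 0.5) * pixel_size, (r + 0.5) * pixel_size)` µm with a top-left
origin, `x` along columns and `y` along rows. Affine transforms are 2×3
matrices mapping moving-image pixel coordinates to fixed-image pixel
coordinates; composition is by homogeneous matrix product, and warping uses
bilinear interpolation with zero padding outside the source. Label masks use
0 for background and positive integers for cells. Cell tables are pandas
DataFrames keyed by `cell_id` with centroids in µm.

## Pixel preprocessing

*Mean ion-count normalisation* divides each SIMS pixel vector by its total
over the p ion channels and multiplies by p, so every non-empty pixel has
channel mean exactly 1 (channel sum p). All-zero pixels stay zero rather
than becoming NaN so that downstream per-cell means remain finite; they are
counted in the returned report. The operation is idempotent, which pins the
interpretation of the normalisation factor (dividing by the channel *mean*;
dividing by the sum instead differs only by the constant p and is available
as `convention="sum"` — no ratio statistic changes either way).

*k-NN denoising* of IMC planes replaces each pixel by the mean of its
spatial neighbours, implemented as a `(2r+1)²` window mean excluding the
centre with r the smallest radius giving at least k neighbours. The filter
statistic and k are not externally constrained, so k = 8 (the 3×3 ring) is
the default and both are configurable; borders use reflected padding.

*Percentile rescaling* clips a plane to its 0.1th/99.9th intensity
percentiles and maps to [0, 1]; constant planes map to zero.

*Density matching* downsamples the denser SIMS grid to the IMC grid with
bi-quadratic (order 2) interpolation, anti-aliasing off. Upsampling is
refused; pixel-size metadata is updated from the area ratio.

## Registration

The SIMS field of view is a small window inside the IMC field, misaligned
by an affine transform (translation, rotation, small shear/scale from
sequential acquisition). Registration uses one reference plane per modality
— a nuclear/DNA marker on the IMC side and the 79 m/z phosphate plane on the
SIMS side — because both depict nuclei.

1. **Coarse search.** Template matching alone cannot locate a strongly
   rotated window, and rotation estimation from FFT magnitude spectra is
   only reliable when both planes show the *same* content (the spectra of
   different windows of a near-isotropic cell field share no stable angular
   features). Rotation and translation are therefore searched jointly but
   cheaply: both planes are downsampled 4-fold and derotations of the moving
   plane are swept in 3° steps, keeping the angle with the highest
   template-match peak of an inscribed sub-window.
2. **Translation.** At full resolution, the derotated moving plane's central
   sub-window (20 % inset, avoiding the empty corners rotation introduces)
   is located by FFT normalised cross-correlation; ties break to the
   lexicographically smallest offset.
3. **Rotation refinement.** With the correct fixed-image crop in hand, the
   angle is re-estimated to 0.1° resolution by 1-D phase correlation of the
   angular marginals of the Hann-windowed, polar-resampled FFT magnitude
   spectra (translation-invariant), with parabolic sub-bin interpolation.
   Magnitude spectra are 180°-symmetric; the ambiguity is resolved by
   image-space correlation after trying both candidates.
4. **Affine refinement.** Difference-of-Gaussian local maxima (σ = 1.6 /
   2.56, relative threshold 0.1) become keypoints described by normalised
   17×17 patches; mutual nearest matching with a 0.8 Lowe ratio feeds a
   seeded RANSAC (3 px residual threshold, 2000 iterations) that fits the
   residual 6-parameter affine, followed by a least-squares refit on the
   inliers. Fewer than 3 inliers raises and the caller falls back to
   rotation + translation.

All stages compose into one transform. Quality is scored on the overlap
region by SSIM (7×7 window, standard constants) and NRMSE after percentile
rescaling, and compared against a seeded random-shift baseline (uniform
within ±25 % of the fixed image size) and a rotation-only baseline. On
synthetic pairs with planted translation, rotation up to 30° and shear/scale
up to 5 %, the composed transform is recovered to sub-pixel corner error and
the SSIM ordering affine ≥ rotation-only ≥ random holds.

## Phenotyping

*Pixel clustering* pools pixels across fields of view, draws a seeded
uniform 1/20 subsample, standardises each channel to mean 0 / sd 1 (constant
channels are dropped with a warning), clusters the subsample with Leiden on
its 15-NN graph and assigns every remaining pixel the majority label among
its 30 nearest sampled pixels in feature space (ties to the lowest label
id). The 1/20 subsample is random rather than strided; the neighbour-graph
k is a free parameter defaulting to 15.

*Cell masks* come from nucleus labels by 2-pixel nearest-label expansion
(`skimage.segmentation.expand_labels`; collisions split at the Euclidean
midline), cytosol = expansion ring. External whole-cell segmenters
(Cellpose, Mesmer) are inputs, not dependencies: the max-projection and
projection-minus-nuclei images they consume are produced on request, and
without an attached segmenter the expansion arithmetic is the fallback.

*Features* are per-channel mean intensities over each cell's mask pixels,
plus centroid (µm) and area (px). *Cell clustering* is Leiden on the 15-NN
graph of z-scored features, with an optional external batch-correction hook
(`hook(X, batches) -> X`, same shape out). *Gating* fits a two-component 1-D
Gaussian mixture (EM, 10 seeded restarts) and thresholds at the posterior
crossover between the component means; degenerate fits (component weight
< 1e-3, or constant input) raise rather than gate.

## Spatial statistics

Neighbour graphs are built either by centroid radius (default 20 µm — one
cell diameter of spacing for ~10 µm cells) or by mask contact after 1 px
binary dilation (for dense tissue). The competition ratio divides a cell's
channel intensity by the mean (default) or median of its neighbours'; the
mean/median discrepancy between natural definitions is resolved as a config
option with the aggregator recorded in the output. Isolated cells and zero
denominators give missing values, never infinities. Ratios are invariant to
global channel rescaling.

Distance gradients bin the 1-NN distance to the gated positive set into 20
equal-width bins over the observed range (equal-width, not quantile) and
min-max normalise per-bin channel means to [0, 1] over non-empty bins;
constant channels are flagged flat and reported as zeros.
Competition-vs-distance curves restrict ratios to each of two cell types
before binning. Neighbourhood signatures count cluster labels within 25 µm
*including the cell itself* (guaranteeing a nonzero total for isolated
cells), normalise to sum 1, and cluster the composition vectors with Leiden;
per-group frequency tables support patient-level comparison.

## Joint variational autoencoder

Two encoder–decoder networks share one latent space: protein P→16→8 and
metabolite M→128→64→32→8 encoders (ReLU), concatenated (16) → dense 16
(ReLU) → linear heads f_µ and f_logvar; σ = exp(½ logvar) (logvar clipped to
±15 for numerical safety). Decoders are 16→16→P and 16→64→128→M with linear
outputs. The loss is MSE per modality (summed over features, averaged over
the batch) plus β times the diagonal-Gaussian KL to the standard normal,
with the reparameterisation z = µ + σ⊙ε. Reconstruction is Gaussian because
both modalities are continuous mean intensities, z-scored per channel before
training (scalers stored on the model). β = 1, Adam at lr 1e-3, batch 256,
100 epochs by default; all randomness (init, shuffling, ε) draws from one
seeded generator, so training is bit-reproducible and single-threaded.

The implementation is plain numpy with hand-written backpropagation: the
networks are small enough that CPU matrix products dominate and an explicit
forward/backward makes the objective directly checkable against hand
computations and finite differences (both tested). Embeddings use µ with no
sampling. Latent dimension is fixed at 16 (two 8-d modality codes); the
metabolite input width is taken from the data, so panels of any size fit.

## Trajectory analysis

Diffusion pseudotime: 15-NN graph on z-scored protein features, Gaussian
kernel with adaptive bandwidth (distance to the k-th neighbour), symmetrised
by the elementwise maximum; the normalised operator's eigenvectors (trivial
one dropped, signs fixed by making each component's largest-magnitude entry
positive) are scaled by λ/(1−λ) and the pseudotime is the Euclidean distance
from the root cell over the top 10 components, min-max normalised to [0, 1].
A disconnected graph raises with the component count. Externally computed
pseudotime can be supplied through a bypass argument. Branches are not
detected automatically: the user declares ordered cluster paths, matching
how bifurcations are read off an embedding plot in practice. Trends use
equal-count pseudotime bins (default 50, reduced with a warning on small
tables) plus per-channel Spearman ρ; spatial arrows point from each cell to
the mean centroid of its 5 nearest neighbours in the next cluster on the
path.

## Synthetic data

The generator plants exactly the structures the statistics measure, on a
tissue simple enough to be checked by brute force:

- **Geometry.** A hard-core point process (minimum centre spacing 8 µm) of
  disk cells (radius 5 µm, i.e. the ~10 µm mean diameter regime) with
  concentric 3 µm nuclei, rendered at 1 µm pixels; one designated vessel
  type (with the CD31-like gate marker) plus three ordinary types.
- **Expression.** Proteins are type-specific means (marker high 8 vs
  baseline 1, secondary markers at 4). Metabolite channel means are baseline
  5 plus uniform(0, 3) type effects — clearly type-dependent profiles, the
  regime a joint embedding is meant to resolve — plus planted fields: an
  exponential vessel-distance decay A·exp(−d/λ) with λ = 60 µm and A = 20
  (λ chosen so the planted channel's Pearson r against distance is below
  −0.9 at zero noise over this field geometry, as the generator guarantees),
  a linear pseudotime trend, and a competition channel where sink-type cells
  gain g = 3 and all other cells are depleted by 1/g (a neighbour-only
  depletion variant is available). Noise is multiplicative lognormal with
  unit mean (default σ = 0.2) so intensities stay positive; σ = 0 reproduces
  the planted means exactly.
- **Imaging.** The IMC stack paints per-cell protein values over cell masks
  plus a DNA channel over nuclei; the SIMS stack paints metabolite values
  plus a phosphate-surrogate channel over nuclei, sampled through a known
  affine misalignment at 2× pixel density over a chosen window, with
  additive Gaussian background noise. The composed ground-truth transform is
  returned for registration checks.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: realistic SIMS fragmentation spectra and peak
overlap, spot blur/point-spread differences between modalities, cell shape
variation and segmentation errors, batch effects between samples, 3-D depth
profiles, and spatially correlated (rather than i.i.d.) noise. Results on
real tissue additionally depend on segmentation quality and channel panel
design, which are inputs here.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes chosen as the
smallest instances that exercise each property: tissues of 120–2,000 cells,
fields of 200–940 µm, 24 registration field-of-view pairs, and a
2,000-cell / 100-epoch VAE run. Every stochastic routine takes an explicit
seed and is deterministic given it; eigen-sign conventions, stable sorts and
lexicographic tie-breaks remove the remaining ambiguity.

## Known limitations

- The SurfaceLab ASCII dialect is not standardised; both supported layouts
  (`long` and `per_channel`) are reasonable guesses to be validated against
  real exports.
- Rotation recovery assumes enough image texture for template matching; a
  nearly empty or periodic field can defeat the coarse sweep.
- The contact-graph builder is exact but quadratic in cell pairs with
  overlapping bounding boxes; for very dense masks the radius graph is the
  practical choice.
- The VAE reconstructs at the noise floor of its input: with 20 %
  multiplicative noise the metabolite modality's reconstruction MAE cannot
  drop much below ~0.67 z-units regardless of capacity, so improvement is
  judged on the pooled two-modality error.
- Competition ratios are undefined (missing) for isolated cells; analyses on
  sparse fields should check the reported neighbour counts.
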