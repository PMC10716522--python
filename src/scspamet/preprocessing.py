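"""Pixel-level normalisation and denoising.

TOF-SIMS ion stacks get per-pixel mean ion-count normalisation: each pixel
vector is divided by its mean intensity over all extracted ion channels, so
that after normalisation every nonzero pixel has channel-mean 1 (equivalently
its channel-sum equals the number of channels p).  IMC marker stacks get a
k-NN mean filter for shot-noise removal and percentile rescaling to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .io_formats import IonImageStack, MarkerImageStack

__all__ = [
    "NormalizationReport",
    "mean_ion_normalize",
    "knn_pixel_denoise",
    "percentile_rescale",
    "match_resolution",
]


@dataclass
class NormalizationReport:
    """Bookkeeping for mean ion-count normalisation.

    ``convention`` records whether pixel vectors were scaled so their channel
    mean is 1 (``"mean"``, i.e. divide by sum and multiply by p) or their
    channel sum is 1 (``"sum"``); the two differ only by the constant factor
    p and leave every ratio statistic unchanged.
    """

    n_zero_pixels: int
    channel_count: int
    per_channel_mean_before: np.ndarray
    per_channel_mean_after: np.ndarray
    convention: str = "mean"


def mean_ion_normalize(
    stack: IonImageStack, convention: str = "mean"
) -> tuple[IonImageStack, NormalizationReport]:
    """Normalise each pixel by its mean intensity over all ion channels.

    For pixel i with channel vector X_i and total t_i = sum_j x_ij > 0 the
    output is Y_i = X_i * p / t_i (so sum_j Y_ij = p and the channel mean is
    exactly 1).  All-zero pixels are left zero and counted in the report.
    """
    if convention not in ("mean", "sum"):
        raise ValueError(f"unknown convention {convention!r}")
    data = stack.data
    if not np.isfinite(data).all():
        raise ValueError("NaN or infinity in ion stack")
    p = data.shape[0]
    total = data.sum(axis=0)
    nonzero = total > 0
    scale = p if convention == "mean" else 1.0
    out = np.zeros_like(data)
    np.divide(data * scale, total[None, :, :], out=out, where=nonzero[None, :, :])
    report = NormalizationReport(
        n_zero_pixels=int((~nonzero).sum()),
        channel_count=p,
        per_channel_mean_before=data.mean(axis=(1, 2)),
        per_channel_mean_after=out.mean(axis=(1, 2)),
        convention=convention,
    )
    return IonImageStack(out, stack.panel, stack.pixel_size_um), report


def _ring_mean(plane: np.ndarray, r: int) -> np.ndarray:
    size = 2 * r + 1
    window_sum = ndimage.uniform_filter(plane, size=size, mode="reflect") * size ** 2
    return (window_sum - plane) / (size ** 2 - 1)


def knn_pixel_denoise(stack: MarkerImageStack, k: int = 8) -> MarkerImageStack:
    """k-NN mean filter: replace every pixel by the mean of its spatial
    neighbours.

    Implemented as a (2r+1) x (2r+1) window mean excluding the centre pixel,
    with r the smallest radius whose window holds at least k neighbours
    (k=8 gives the 3x3 ring).  Border pixels use reflected padding.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    h, w = stack.data.shape[1:]
    if k >= h * w:
        raise ValueError(f"k={k} exceeds image size {h}x{w}")
    r = 1
    while (2 * r + 1) ** 2 - 1 < k:
        r += 1
    out = np.stack([_ring_mean(plane, r) for plane in stack.data])
    return MarkerImageStack(out, stack.panel, stack.pixel_size_um)


def percentile_rescale(plane: np.ndarray, lo: float = 0.1, hi: float = 99.9) -> np.ndarray:
    """Clip a plane to its [lo, hi] intensity percentiles and map to [0, 1].

    A constant plane maps to all zeros.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    plane = np.asarray(plane, dtype=np.float64)
    p_lo, p_hi = np.percentile(plane, [lo, hi])
    if p_hi <= p_lo:
        return np.zeros_like(plane)
    return (np.clip(plane, p_lo, p_hi) - p_lo) / (p_hi - p_lo)


def match_resolution(stack: IonImageStack, target_hw: tuple[int, int]) -> IonImageStack:
    """Downsample a higher-density SIMS stack to the IMC grid.

    Uses bi-quadratic (order-2) interpolation with anti-aliasing disabled.
    Upsampling is out of scope and raises.
    """
    h, w = stack.data.shape[1:]
    th, tw = target_hw
    if th > h or tw > w:
        raise ValueError(f"match_resolution only downsamples: {h}x{w} -> {th}x{tw}")
    if (th, tw) == (h, w):
        return IonImageStack(stack.data.copy(), stack.panel, stack.pixel_size_um)
    out = np.stack(
        [
            resize(plane, (th, tw), order=2, anti_aliasing=False, preserve_range=True)
            for plane in stack.data
        ]
    )
    # intensities are densities per pixel; interpolation preserves values
    out = np.clip(out, 0, None)
    new_ps = stack.pixel_size_um * math.sqrt((h * w) / (th * tw))
    return IonImageStack(out, stack.panel, new_ps)
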