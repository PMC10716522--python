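"""Three-stage cross-modality image registration.

The SIMS field of view is a small, possibly rotated/sheared window inside the
larger IMC field.  Registration runs on one reference plane per modality
(nuclear marker on the IMC side, the phosphate ion plane on the SIMS side):

1. *template matching* — FFT normalised cross-correlation locates the SIMS
   window inside the IMC image (translation);
2. *rotation* — 1-D phase correlation of the angular marginals of the
   polar-resampled FFT magnitude spectra (translation-invariant) recovers the
   rotation offset, with the 180 degree spectrum ambiguity resolved by
   image-space correlation;
3. *affine refinement* — Difference-of-Gaussian keypoints with normalised
   patch descriptors, ratio-test matching and seeded RANSAC fit the residual
   6-parameter affine.

All stages compose into a single 2 x 3 affine mapping moving-image pixel
coordinates (x = col, y = row) to fixed-image pixel coordinates.  Quality is
scored by SSIM and NRMSE on the overlap region, and the same scoring applies
to the random-shift and rotation-only baseline comparators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from skimage import transform as sktransform
from skimage.feature import match_template, peak_local_max
from skimage.filters import gaussian, window as sk_window
from skimage.measure import ransac
from skimage.metrics import structural_similarity

from .io_formats import IonImageStack, MarkerImageStack
from .preprocessing import match_resolution, percentile_rescale

__all__ = [
    "AffineTransform2D",
    "RegistrationConfig",
    "RegistrationResult",
    "locate_template",
    "estimate_rotation",
    "refine_affine",
    "register",
    "score_registration",
    "baseline_transforms",
]


@dataclass(frozen=True)
class AffineTransform2D:
    """2 x 3 affine mapping moving (x, y) to fixed (x, y) pixel coordinates."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2 x 3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) <= 1e-8:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def matrix3(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to n x 2 (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return AffineTransform2D((self.matrix3 @ other.matrix3)[:2])

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D(np.linalg.inv(self.matrix3)[:2])

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, dx], [0.0, 1.0, dy]]))

    @classmethod
    def rotation(cls, degrees: float, center: tuple[float, float] = (0.0, 0.0)) -> "AffineTransform2D":
        """Rotation by ``degrees`` about ``center`` (x, y); positive angles
        rotate from +x towards +y (clockwise on screen with y down)."""
        th = np.deg2rad(degrees)
        c, s = np.cos(th), np.sin(th)
        cx, cy = center
        tx = cx - c * cx + s * cy
        ty = cy - s * cx - c * cy
        return cls(np.array([[c, -s, tx], [s, c, ty]]))

    @classmethod
    def scaling(cls, factor: float, offset: float = 0.0) -> "AffineTransform2D":
        return cls(np.array([[factor, 0.0, offset], [0.0, factor, offset]]))

    def warp(self, moving: np.ndarray, output_shape: tuple[int, int], order: int = 1) -> np.ndarray:
        """Resample ``moving`` onto the fixed grid (bilinear, zero padding)."""
        inv = sktransform.AffineTransform(matrix=self.inverse().matrix3)
        return sktransform.warp(
            moving, inverse_map=inv, output_shape=output_shape, order=order,
            mode="constant", cval=0.0, preserve_range=True,
        )


def _downsample_transform(src_hw, dst_hw) -> AffineTransform2D:
    # pixel-centre convention of skimage.transform.resize
    fy = dst_hw[0] / src_hw[0]
    fx = dst_hw[1] / src_hw[1]
    return AffineTransform2D(
        np.array([[fx, 0.0, 0.5 * fx - 0.5], [0.0, fy, 0.5 * fy - 0.5]])
    )


# ---------------------------------------------------------------------------
# stage 1: template matching
# ---------------------------------------------------------------------------

def locate_template(fixed_large: np.ndarray, moving_small: np.ndarray):
    """Find the SIMS window inside the IMC plane by normalised cross-correlation.

    Returns ``(dy, dx, corr_peak, fixed_crop)`` where ``fixed_crop`` is the
    best-matching sub-window of the fixed plane with the moving plane's shape.
    Ties are broken by the lexicographically smallest (dy, dx).
    """
    fixed_large = np.asarray(fixed_large, dtype=float)
    moving_small = np.asarray(moving_small, dtype=float)
    if moving_small.shape[0] > fixed_large.shape[0] or moving_small.shape[1] > fixed_large.shape[1]:
        raise ValueError("moving plane larger than fixed plane")
    if np.std(moving_small) == 0:
        raise ValueError("moving plane has zero variance; correlation undefined")
    response = match_template(fixed_large, moving_small, pad_input=False)
    peak = response.max()
    candidates = np.argwhere(response >= peak - 1e-12)
    dy, dx = min(map(tuple, candidates))
    crop = fixed_large[dy : dy + moving_small.shape[0], dx : dx + moving_small.shape[1]]
    return int(dy), int(dx), float(peak), crop


# ---------------------------------------------------------------------------
# stage 2: rotation via polar-resampled magnitude spectra
# ---------------------------------------------------------------------------

def _angular_marginal(plane: np.ndarray, n_angles: int) -> np.ndarray:
    win = sk_window("hann", plane.shape)
    spec = np.abs(np.fft.fftshift(np.fft.fft2(plane * win)))
    spec = np.log1p(spec)
    radius = min(plane.shape) // 2
    polar = sktransform.warp_polar(
        spec, radius=radius, output_shape=(n_angles, radius), order=1
    )
    # suppress the DC-dominated centre
    return polar[:, max(2, radius // 20):].sum(axis=1)


def _masked_corr(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    a = a[mask]
    b = b[mask]
    if a.size < 10 or np.std(a) == 0 or np.std(b) == 0:
        return -np.inf
    return float(np.corrcoef(a, b)[0, 1])


def estimate_rotation(
    fixed_crop: np.ndarray, moving: np.ndarray, angle_res_deg: float = 0.1
) -> float:
    """Rotation angle (degrees) of the moving-to-fixed point map.

    Computes the FFT magnitude spectra of both planes (translation drops
    out), resamples them onto a polar grid, and phase-correlates the angular
    marginals.  The magnitude spectrum is 180-degree symmetric, so the two
    candidates theta and theta + 180 are disambiguated by image-space
    correlation after derotation.  Result lies in (-180, 180].
    """
    fixed_crop = np.asarray(fixed_crop, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed_crop.shape != moving.shape:
        raise ValueError("planes must share a shape")
    if np.all(fixed_crop == 0) or np.all(moving == 0):
        raise ValueError("all-zero plane; rotation undefined")
    n_angles = max(int(round(360.0 / angle_res_deg)), 360)
    mf = _angular_marginal(fixed_crop, n_angles)
    mm = _angular_marginal(moving, n_angles)
    mf = mf - mf.mean()
    mm = mm - mm.mean()
    corr = np.real(np.fft.ifft(np.fft.fft(mf) * np.conj(np.fft.fft(mm))))
    shift = int(np.argmax(corr))
    # parabolic sub-bin refinement
    c0, c1, c2 = corr[(shift - 1) % n_angles], corr[shift], corr[(shift + 1) % n_angles]
    denom = c0 - 2 * c1 + c2
    frac = 0.0 if denom == 0 else 0.5 * (c0 - c2) / denom
    theta = (shift + frac) * 360.0 / n_angles
    if theta > 180.0:
        theta -= 360.0

    h, w = moving.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    best = (-np.inf, theta)
    for cand in (theta, theta + 180.0 if theta <= 0 else theta - 180.0):
        t = AffineTransform2D.rotation(cand, center)
        derot = t.warp(moving, moving.shape)
        support = t.warp(np.ones_like(moving), moving.shape) > 0.5
        score = _masked_corr(fixed_crop, derot, support)
        if score > best[0]:
            best = (score, cand)
    theta = best[1]
    if theta <= -180.0:
        theta += 360.0
    elif theta > 180.0:
        theta -= 360.0
    return float(theta)


# ---------------------------------------------------------------------------
# stage 3: DoG keypoints + RANSAC affine
# ---------------------------------------------------------------------------

def _dog_keypoints(plane: np.ndarray, sigma_low: float, sigma_high: float,
                   threshold_rel: float, patch_radius: int) -> np.ndarray:
    dog = gaussian(plane, sigma_low, preserve_range=True) - gaussian(
        plane, sigma_high, preserve_range=True
    )
    if dog.max() <= 0:
        return np.empty((0, 2), dtype=int)
    peaks = peak_local_max(
        dog,
        min_distance=3,
        threshold_abs=threshold_rel * dog.max(),
        exclude_border=patch_radius + 1,
    )
    return peaks  # (row, col)


def _patch_descriptors(plane: np.ndarray, peaks: np.ndarray, radius: int):
    smooth = gaussian(plane, 1.0, preserve_range=True)
    desc, kept = [], []
    for r, c in peaks:
        patch = smooth[r - radius : r + radius + 1, c - radius : c + radius + 1]
        v = patch.ravel().astype(float)
        v = v - v.mean()
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        desc.append(v / norm)
        kept.append((r, c))
    return np.asarray(desc), np.asarray(kept, dtype=float).reshape(-1, 2)


def _coarse_rotation_search(
    fixed: np.ndarray, moving: np.ndarray, step_deg: float = 3.0, pyramid: int = 4
) -> float:
    """Best rotation angle by sweeping derotations of a downsampled moving
    plane against the downsampled fixed plane (template-match peak height).

    Resolves where spectrum-based estimation cannot: the fixed window
    containing the moving image is unknown, so rotation and translation must
    be searched jointly; a coarse pyramid sweep keeps that cheap.
    """
    fs = sktransform.resize(
        fixed, (fixed.shape[0] // pyramid, fixed.shape[1] // pyramid),
        anti_aliasing=True, preserve_range=True,
    )
    ms = sktransform.resize(
        moving, (max(moving.shape[0] // pyramid, 8), max(moving.shape[1] // pyramid, 8)),
        anti_aliasing=True, preserve_range=True,
    )
    h, w = ms.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    m0 = max(int(0.25 * min(h, w)), 1)
    best = (-np.inf, 0.0)
    for ang in np.arange(-180.0, 180.0, step_deg):
        rtf = AffineTransform2D.rotation(ang, center)
        der = rtf.warp(ms, ms.shape)
        sub = der[m0 : h - m0, m0 : w - m0]
        if np.std(sub) == 0:
            continue
        resp = match_template(fs, sub, pad_input=False)
        pk = resp.max()
        if pk > best[0]:
            best = (pk, float(ang))
    return best[1]


def _estimate_affine(src: np.ndarray, dst: np.ndarray):
    """Least-squares affine fit src -> dst; None on degenerate input."""
    tf = sktransform.AffineTransform()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        ok = tf.estimate(src, dst)
    return tf if ok else None


def _match_descriptors(d_src, d_dst, ratio: float) -> np.ndarray:
    if len(d_src) == 0 or len(d_dst) == 0:
        return np.empty((0, 2), dtype=int)
    dist = cdist(d_src, d_dst)
    fwd = np.argmin(dist, axis=1)
    matches = []
    for i, j in enumerate(fwd):
        row = np.sort(dist[i])
        if len(row) > 1 and row[0] > ratio * row[1]:
            continue
        if np.argmin(dist[:, j]) != i:  # mutual check
            continue
        matches.append((i, j))
    return np.asarray(matches, dtype=int).reshape(-1, 2)


def refine_affine(
    fixed_crop: np.ndarray,
    moving_derotated: np.ndarray,
    dog_sigma_low: float = 1.6,
    dog_sigma_high: float = 2.56,
    match_ratio: float = 0.8,
    ransac_thresh_px: float = 3.0,
    ransac_iters: int = 2000,
    seed: int = 0,
    dog_threshold_rel: float = 0.1,
    patch_radius: int = 8,
) -> AffineTransform2D:
    """Fit the residual affine (moving-derotated -> fixed-crop coordinates).

    DoG local maxima above a relative threshold are keypoints, described by
    mean/norm-normalised local patches, matched mutually with a Lowe ratio
    test, then a seeded RANSAC fits the 6-parameter affine with a final
    least-squares refit on the inlier set.  Raises if the affine is
    underdetermined (< 3 inliers); callers fall back to rotation+translation.
    """
    kp_f = _dog_keypoints(fixed_crop, dog_sigma_low, dog_sigma_high,
                          dog_threshold_rel, patch_radius)
    kp_m = _dog_keypoints(moving_derotated, dog_sigma_low, dog_sigma_high,
                          dog_threshold_rel, patch_radius)
    d_f, kp_f = _patch_descriptors(fixed_crop, kp_f, patch_radius)
    d_m, kp_m = _patch_descriptors(moving_derotated, kp_m, patch_radius)
    if len(kp_f) < 3 or len(kp_m) < 3:
        raise ValueError("affine underdetermined: fewer than 3 keypoints")
    matches = _match_descriptors(d_m, d_f, match_ratio)
    if len(matches) < 3:
        raise ValueError("affine underdetermined: fewer than 3 matches")
    src = kp_m[matches[:, 0]][:, ::-1]  # (x, y)
    dst = kp_f[matches[:, 1]][:, ::-1]
    if len(matches) == 3:
        model = _estimate_affine(src, dst)
        if model is None:
            raise ValueError("affine underdetermined: degenerate matches")
        inliers = np.ones(3, dtype=bool)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, inliers = ransac(
                (src, dst),
                sktransform.AffineTransform,
                min_samples=3,
                residual_threshold=ransac_thresh_px,
                max_trials=ransac_iters,
                rng=seed,
            )
    if model is None or inliers is None or inliers.sum() < 3:
        raise ValueError("affine underdetermined: fewer than 3 RANSAC inliers")
    refit = _estimate_affine(src[inliers], dst[inliers])
    if refit is None:
        raise ValueError("affine underdetermined: refit failed")
    return AffineTransform2D(refit.params[:2])


# ---------------------------------------------------------------------------
# scoring and the full pipeline
# ---------------------------------------------------------------------------

def score_registration(fixed_crop: np.ndarray, warped_moving: np.ndarray):
    """(SSIM, NRMSE) of two same-shape planes after percentile rescaling.

    SSIM uses a 7 x 7 window with the standard constants; NRMSE is the RMSE
    divided by the fixed plane's intensity range (1 after rescaling).
    """
    fixed_crop = np.asarray(fixed_crop, dtype=float)
    warped_moving = np.asarray(warped_moving, dtype=float)
    if fixed_crop.shape != warped_moving.shape:
        raise ValueError("planes must share a shape")
    if np.max(fixed_crop) == np.min(fixed_crop):
        raise ValueError("constant fixed plane; NRMSE undefined")
    a = percentile_rescale(fixed_crop)
    b = percentile_rescale(warped_moving)
    ssim = structural_similarity(a, b, win_size=7, data_range=1.0)
    nrmse = float(np.sqrt(np.mean((a - b) ** 2)))
    return float(ssim), nrmse


@dataclass
class RegistrationConfig:
    fixed_ref: str = "DNA"
    moving_ref: str = "PO3"
    angle_res_deg: float = 0.1
    dog_sigma_low: float = 1.6
    dog_sigma_high: float = 2.56
    dog_threshold_rel: float = 0.1
    match_ratio: float = 0.8
    ransac_thresh_px: float = 3.0
    ransac_iters: int = 2000
    seed: int = 0
    refine: bool = True
    coarse_step_deg: float = 3.0


@dataclass
class RegistrationResult:
    translation_px: tuple[int, int]  # (dy, dx)
    rotation_deg: float
    affine: AffineTransform2D
    ssim: float
    nrmse: float
    corr_peak: float
    refined: bool = True

    def to_dict(self) -> dict:
        return {
            "translation_px": list(self.translation_px),
            "rotation_deg": self.rotation_deg,
            "affine_matrix": self.affine.matrix.ravel().tolist(),
            "ssim": self.ssim,
            "nrmse": self.nrmse,
            "corr_peak": self.corr_peak,
            "refined": self.refined,
        }


def _score_transform(fixed_ref: np.ndarray, moving_ref: np.ndarray,
                     affine: AffineTransform2D):
    warped = affine.warp(moving_ref, fixed_ref.shape)
    support = affine.warp(np.ones_like(moving_ref), fixed_ref.shape) > 0.5
    if not support.any():
        return -1.0, 1.0
    rows = np.any(support, axis=1)
    cols = np.any(support, axis=0)
    r0, r1 = np.argmax(rows), len(rows) - np.argmax(rows[::-1])
    c0, c1 = np.argmax(cols), len(cols) - np.argmax(cols[::-1])
    if r1 - r0 < 8 or c1 - c0 < 8:
        return -1.0, 1.0
    return score_registration(fixed_ref[r0:r1, c0:c1], warped[r0:r1, c0:c1])


def register(
    fixed: MarkerImageStack,
    moving: IonImageStack,
    config: Optional[RegistrationConfig] = None,
) -> RegistrationResult:
    """Run the full three-stage registration on the reference planes.

    Pipeline: density matching (downsample SIMS to the IMC pixel size) ->
    template matching -> rotation -> affine refinement, composed into one
    moving-to-fixed :class:`AffineTransform2D`; the moving reference plane is
    warped by bilinear interpolation and scored (SSIM / NRMSE) on the overlap.
    """
    config = config or RegistrationConfig()
    fixed_ref = fixed.plane(config.fixed_ref)
    moving_ref_full = moving.plane(config.moving_ref)

    # stage 0: match pixel densities using the known pixel sizes
    factor = moving.pixel_size_um / fixed.pixel_size_um
    target_hw = (
        max(int(round(moving.data.shape[1] * factor)), 1),
        max(int(round(moving.data.shape[2] * factor)), 1),
    )
    try:
        moving_ds = match_resolution(moving, target_hw)
    except ValueError as exc:
        raise ValueError(f"match_resolution failed: {exc}") from exc
    d_tf = _downsample_transform(moving.data.shape[1:], target_hw)
    moving_ref = moving_ds.plane(config.moving_ref)
    h, w = moving_ref.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    H, W = fixed_ref.shape

    # coarse joint rotation/translation search on a downsampled pyramid
    # (template matching alone cannot locate a strongly rotated window)
    theta0 = _coarse_rotation_search(fixed_ref, moving_ref, config.coarse_step_deg)

    # locate at full resolution with an inscribed sub-window of the
    # derotated moving plane (its corners are empty after rotation)
    m0 = int(0.2 * min(h, w))
    rtf = AffineTransform2D.rotation(theta0, center)
    der = rtf.warp(moving_ref, moving_ref.shape)
    sub = der[m0 : h - m0, m0 : w - m0]
    try:
        sy, sx, peak, _ = locate_template(fixed_ref, sub)
    except ValueError as exc:
        raise ValueError(f"locate_template failed: {exc}") from exc
    dy = int(np.clip(sy - m0, 0, H - h))
    dx = int(np.clip(sx - m0, 0, W - w))
    crop = fixed_ref[dy : dy + h, dx : dx + w]
    off_tf = AffineTransform2D.translation(dx, dy)

    # second pass on the true window for full angular accuracy
    try:
        theta = estimate_rotation(crop, moving_ref, config.angle_res_deg)
    except ValueError:
        theta = theta0
    rot_tf = AffineTransform2D.rotation(theta, center)
    derot = rot_tf.warp(moving_ref, moving_ref.shape)

    refined = False
    aff_tf = AffineTransform2D.identity()
    if config.refine:
        try:
            aff_tf = refine_affine(
                crop, derot,
                dog_sigma_low=config.dog_sigma_low,
                dog_sigma_high=config.dog_sigma_high,
                match_ratio=config.match_ratio,
                ransac_thresh_px=config.ransac_thresh_px,
                ransac_iters=config.ransac_iters,
                seed=config.seed,
                dog_threshold_rel=config.dog_threshold_rel,
            )
            refined = True
        except ValueError:
            aff_tf = AffineTransform2D.identity()

    total = off_tf.compose(aff_tf).compose(rot_tf).compose(d_tf)
    ssim, nrmse = _score_transform(fixed_ref, moving_ref_full, total)
    return RegistrationResult(
        translation_px=(dy, dx),
        rotation_deg=theta,
        affine=total,
        ssim=ssim,
        nrmse=nrmse,
        corr_peak=peak,
        refined=refined,
    )


def baseline_transforms(
    fixed: MarkerImageStack,
    moving: IonImageStack,
    result: RegistrationResult,
    config: Optional[RegistrationConfig] = None,
    seed: int = 0,
) -> dict:
    """Baseline comparators scored identically to the full registration.

    ``random_shift`` places the SIMS window at the template position plus a
    seeded uniform shift within +-25 % of the fixed image size (no rotation);
    ``rotation_only`` composes the translation and rotation stages without
    affine refinement.
    """
    config = config or RegistrationConfig()
    fixed_ref = fixed.plane(config.fixed_ref)
    moving_ref = moving.plane(config.moving_ref)
    factor = moving.pixel_size_um / fixed.pixel_size_um
    target_hw = (
        max(int(round(moving.data.shape[1] * factor)), 1),
        max(int(round(moving.data.shape[2] * factor)), 1),
    )
    d_tf = _downsample_transform(moving.data.shape[1:], target_hw)
    dy, dx = result.translation_px
    rng = np.random.default_rng(seed)
    H, W = fixed_ref.shape
    h, w = target_hw
    rdy = int(np.clip(dy + rng.uniform(-0.25 * H, 0.25 * H), 0, H - h))
    rdx = int(np.clip(dx + rng.uniform(-0.25 * W, 0.25 * W), 0, W - w))
    rand_tf = AffineTransform2D.translation(rdx, rdy).compose(d_tf)
    ssim_r, nrmse_r = _score_transform(fixed_ref, moving_ref, rand_tf)
    random_res = RegistrationResult((rdy, rdx), 0.0, rand_tf, ssim_r, nrmse_r,
                                    result.corr_peak, refined=False)

    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    rot_tf = (
        AffineTransform2D.translation(dx, dy)
        .compose(AffineTransform2D.rotation(result.rotation_deg, center))
        .compose(d_tf)
    )
    ssim_o, nrmse_o = _score_transform(fixed_ref, moving_ref, rot_tf)
    rotation_res = RegistrationResult((dy, dx), result.rotation_deg, rot_tf,
                                      ssim_o, nrmse_o, result.corr_peak, refined=False)
    return {"random_shift": random_res, "rotation_only": rotation_res}
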