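"""Local image cues to surface tilt computed from stereo image pairs.

Three unsigned orientation cues are measured at the patch center:

* luminance cue — orientation of the Gaussian-derivative luminance gradient;
* disparity cue — orientation of the gradient of the disparity map, which is
  recovered from the left/right pair by local windowed cross-correlation;
* texture cue — orientation of the major axis of the local amplitude
  spectrum of the luminance image.

All orientations are reduced modulo 180 (the analysis domain is unsigned
tilt). Local luminance contrast is the Weber-normalized, cosine-windowed
RMS contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CueConfig",
    "CueTriplet",
    "local_contrast",
    "luminance_cue",
    "disparity_map",
    "disparity_cue",
    "texture_cue",
    "compute_cue_triplet",
]


@dataclass(frozen=True)
class CueConfig:
    """Configuration for cue computation.

    ``sigma_cue_arcmin`` is the space constant of the Gaussian-derivative
    operator and of the cross-correlation window (the same constant is used
    for both). Qualitative results are stable for sigma in {3, 6, 9, 12}
    arcmin.
    """

    sigma_cue_arcmin: float = 6.0
    pixels_per_degree: float = 1920.0 / 36.0
    disparity_search_range_px: int = 16
    texture_window_deg: float = 1.0
    contrast_window_diameter_deg: float = 1.0
    corr_threshold: float = 0.3
    spectrum_lowfreq_cutoff_cpd: float = 1.0
    anisotropy_min_ratio: float = 1.15
    gradient_rel_eps: float = 1e-9

    def __post_init__(self):
        if self.sigma_cue_arcmin <= 0:
            raise ValueError("sigma_cue_arcmin must be positive")

    @property
    def sigma_px(self) -> float:
        return self.sigma_cue_arcmin / 60.0 * self.pixels_per_degree


@dataclass
class CueTriplet:
    """Three unsigned orientation cues (deg, [0,180)) plus reliability flags.

    Unreliable cues are NaN with the corresponding flag set to False.
    """

    lum_cue: float
    disp_cue: float
    tex_cue: float
    lum_ok: bool = True
    disp_ok: bool = True
    tex_ok: bool = True
    contrast: float = float("nan")

    @property
    def all_ok(self) -> bool:
        return self.lum_ok and self.disp_ok and self.tex_ok

    def as_array(self) -> np.ndarray:
        return np.array([self.lum_cue, self.disp_cue, self.tex_cue], dtype=float)


class MeanLuminanceError(ValueError):
    """Raised when the windowed mean luminance is non-positive."""


def _raised_cosine_window(shape: tuple[int, int], diameter_px: float) -> np.ndarray:
    rows, cols = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r = np.hypot(rows - cy, cols - cx)
    radius = diameter_px / 2.0
    w = 0.5 * (1.0 + np.cos(np.pi * np.minimum(r / radius, 1.0)))
    w[r > radius] = 0.0
    return w


def local_contrast(image: np.ndarray, cfg: CueConfig | None = None, weights=None) -> float:
    """Weber RMS contrast in a cosine-windowed local area.

    ``sqrt( sum ((I - Ibar)/Ibar)^2 W / sum W )`` with ``Ibar`` the
    W-weighted mean. ``weights`` overrides the default raised-cosine window
    (useful for hand-checkable toy cases).
    """
    cfg = cfg or CueConfig()
    img = np.asarray(image, dtype=float)
    if weights is None:
        diam = cfg.contrast_window_diameter_deg * cfg.pixels_per_degree
        weights = _raised_cosine_window(img.shape, diam)
    w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    mean = float((img * w).sum() / wsum)
    if mean <= 0:
        raise MeanLuminanceError("windowed mean luminance must be positive")
    dev2 = ((img - mean) / mean) ** 2
    return float(np.sqrt((dev2 * w).sum() / wsum))


def _center_gradient(arr: np.ndarray, sigma_px: float) -> tuple[float, float]:
    """Gaussian-derivative gradient (gx, gy) at the array center, y-up."""
    a = np.asarray(arr, dtype=float)
    gx = ndimage.gaussian_filter(a, sigma_px, order=(0, 1), mode="reflect", truncate=3.0)
    g_row = ndimage.gaussian_filter(a, sigma_px, order=(1, 0), mode="reflect", truncate=3.0)
    cy, cx = a.shape[0] // 2, a.shape[1] // 2
    return float(gx[cy, cx]), float(-g_row[cy, cx])


def _gradient_orientation(gx: float, gy: float, eps: float) -> tuple[float, bool]:
    mag = float(np.hypot(gx, gy))
    if mag < eps:
        return float("nan"), False
    return float(np.degrees(np.arctan2(gy, gx)) % 180.0), True


def luminance_cue(image: np.ndarray, cfg: CueConfig | None = None) -> tuple[float, bool]:
    """Orientation (deg mod 180) of the luminance gradient at patch center."""
    cfg = cfg or CueConfig()
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    gx, gy = _center_gradient(img, cfg.sigma_px)
    scale = max(float(np.abs(img).mean()), 1e-30)
    return _gradient_orientation(gx, gy, cfg.gradient_rel_eps * scale)


def disparity_map(
    left: np.ndarray,
    right: np.ndarray,
    cfg: CueConfig | None = None,
    search_range_px: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal disparity (px, signed) by local windowed cross-correlation.

    For each pixel, the integer shift maximizing Gaussian-windowed
    normalized cross-correlation between the left image and the shifted
    right image is found within +/- the search range and refined to
    sub-pixel precision by parabolic interpolation of the correlation peak.
    Disparity is ``x_left - x_right`` of corresponding points: positive for
    surfaces nearer than the convergence distance (for parallel viewing
    axes, positive everywhere).

    Returns ``(disparity, valid)`` where ``valid`` flags pixels whose peak
    correlation exceeds ``cfg.corr_threshold`` and is interior to the search
    range. Pixels within a search-range margin of the left/right image
    borders are marked invalid (shift wrap-around).
    """
    cfg = cfg or CueConfig()
    L = np.asarray(left, dtype=float)
    R = np.asarray(right, dtype=float)
    if L.shape != R.shape or L.ndim != 2:
        raise ValueError("left/right must be equal-size 2D images")
    rng_px = int(search_range_px if search_range_px is not None else cfg.disparity_search_range_px)
    sigma = cfg.sigma_px

    def blur(a):
        return ndimage.gaussian_filter(a, sigma, mode="reflect", truncate=3.0)

    muL = blur(L)
    varL = np.maximum(blur(L * L) - muL * muL, 0.0)
    shifts = np.arange(-rng_px, rng_px + 1)
    ncc = np.full((shifts.size, *L.shape), -np.inf)
    tiny = 1e-12 * max(float(varL.max()), 1e-30)
    for s_idx, s in enumerate(shifts):
        # R(x - s): shift right-image columns by +s
        Rs = np.roll(R, s, axis=1)
        muRs = blur(Rs)
        varRs = np.maximum(blur(Rs * Rs) - muRs * muRs, 0.0)
        cov = blur(L * Rs) - muL * muRs
        denom = np.sqrt(np.maximum(varL * varRs, tiny))
        ncc[s_idx] = cov / denom
    best = np.argmax(ncc, axis=0)
    peak = np.take_along_axis(ncc, best[None], axis=0)[0]
    interior = (best > 0) & (best < shifts.size - 1)
    b = np.clip(best, 1, shifts.size - 2)
    rows, cols = np.indices(L.shape)
    c0 = ncc[b - 1, rows, cols]
    c1 = ncc[b, rows, cols]
    c2 = ncc[b + 1, rows, cols]
    curv = c0 - 2.0 * c1 + c2
    offset = np.where(np.abs(curv) > 1e-12, 0.5 * (c0 - c2) / np.where(curv == 0, 1, curv), 0.0)
    offset = np.clip(offset, -0.5, 0.5)
    disp = shifts[b] + offset
    valid = interior & (peak >= cfg.corr_threshold) & np.isfinite(disp)
    # shift wrap-around plus window support contaminate a border band whose
    # width depends on the local disparity magnitude
    margin = np.ceil(np.abs(disp)) + np.ceil(3.0 * sigma) + 1
    valid &= (cols >= margin) & (cols <= L.shape[1] - 1 - margin)
    return disp, valid


def disparity_cue(
    disparity: np.ndarray,
    cfg: CueConfig | None = None,
    valid: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Orientation (deg mod 180) of the disparity-map gradient at center."""
    cfg = cfg or CueConfig()
    d = np.asarray(disparity, dtype=float)
    if valid is not None:
        # require a reliable neighborhood over the bulk of the kernel support
        half = max(int(np.ceil(2.0 * cfg.sigma_px)), 1)
        cy, cx = d.shape[0] // 2, d.shape[1] // 2
        nb = valid[
            max(cy - half, 0) : cy + half + 1,
            max(cx - half, 0) : cx + half + 1,
        ]
        if not np.all(nb):
            return float("nan"), False
    gx, gy = _center_gradient(d, cfg.sigma_px)
    return _gradient_orientation(gx, gy, 1e-6)


def texture_cue(image: np.ndarray, cfg: CueConfig | None = None) -> tuple[float, bool]:
    """Orientation of the major axis of the local amplitude spectrum.

    A Hann-windowed FFT is taken over the central window; DC and radial
    frequencies below the low-frequency cutoff are removed; the orientation
    of the principal eigenvector of the second-moment matrix of amplitude
    over frequency coordinates is returned (mod 180). Near-isotropic spectra
    (eigenvalue ratio below ``anisotropy_min_ratio``) are flagged unreliable.
    """
    cfg = cfg or CueConfig()
    img = np.asarray(image, dtype=float)
    n = int(round(cfg.texture_window_deg * cfg.pixels_per_degree))
    n = min(n, *img.shape)
    if n < 8:
        raise ValueError("texture window too small")
    cy, cx = img.shape[0] // 2, img.shape[1] // 2
    half = n // 2
    win = img[cy - half : cy - half + n, cx - half : cx - half + n]
    hann = np.hanning(n)
    tapered = (win - win.mean()) * np.outer(hann, hann)
    amp = np.abs(np.fft.fftshift(np.fft.fft2(tapered)))
    f = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / cfg.pixels_per_degree))  # cpd
    fx, fyr = np.meshgrid(f, f)
    fy = -fyr  # y-up in the frequency plane as well
    radial = np.hypot(fx, fy)
    mask = radial >= cfg.spectrum_lowfreq_cutoff_cpd
    a = amp * mask
    total = a.sum()
    if total <= 0:
        return float("nan"), False
    mxx = (a * fx * fx).sum() / total
    myy = (a * fy * fy).sum() / total
    mxy = (a * fx * fy).sum() / total
    m = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(m)
    lam_minor, lam_major = evals
    if lam_minor <= 0 or lam_major / lam_minor < cfg.anisotropy_min_ratio:
        return float("nan"), False
    v = evecs[:, 1]
    return float(np.degrees(np.arctan2(v[1], v[0])) % 180.0), True


def compute_cue_triplet(patch, cfg: CueConfig | None = None) -> CueTriplet:
    """Assemble the three cues (and contrast) at the center of a stereo patch.

    ``patch`` must expose ``left_image`` and ``right_image`` arrays (any
    object with those attributes, e.g. ``stereo_synth.StereoPatch``).
    Deterministic for fixed inputs.
    """
    cfg = cfg or CueConfig()
    lum, lum_ok = luminance_cue(patch.left_image, cfg)
    disp_arr, valid = disparity_map(patch.left_image, patch.right_image, cfg)
    disp, disp_ok = disparity_cue(disp_arr, cfg, valid=valid)
    tex, tex_ok = texture_cue(patch.left_image, cfg)
    contrast = local_contrast(patch.left_image, cfg)
    return CueTriplet(
        lum_cue=lum,
        disp_cue=disp,
        tex_cue=tex,
        lum_ok=lum_ok,
        disp_ok=disp_ok,
        tex_ok=tex_ok,
        contrast=contrast,
    )
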