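"""Synthetic stereo scenes with pixel-registered range maps.

Generates textured planar (optionally bumpy) surfaces at configurable
tilt/slant/distance, rendered by inverse ray casting to a left-eye image, a
right-eye image and a cyclopean range map. Stands in for a natural-scene
stereo database: a cardinal-heavy tilt prior can be emulated by mixing
ground-plane-like and trunk-like patches, local depth structure by smooth
random height perturbations, and human responses by a synthetic observer
(axial von-Mises noise plus lapses).

Conventions: the cyclopean eye is at the origin looking along +z; x is
rightward, y is up. A plane with tilt tau and slant s has unit normal
``(-sin s cos tau, -sin s sin tau, cos s)`` so that the range gradient in
the image points in direction tau (tilt 90 = ground-plane-like, range
increasing with elevation). Eye images use a shifted-sensor (asymmetric
frustum) projection converged at the patch-center distance by default, so
epipolar lines are horizontal and disparity is ``f * b * (1/z - 1/dc)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from . import image_cues, surface_truth
from .circstats import circ_error

__all__ = [
    "ViewingGeometry",
    "SceneSpec",
    "StereoPatch",
    "SamplingConstraints",
    "SyntheticObserverSpec",
    "TEXTURE_KINDS",
    "UnknownTextureError",
    "make_texture",
    "perturb_surface",
    "render_stereo",
    "sample_stimuli",
    "sample_tilt_prior",
    "sample_database_patches",
    "simulate_cue_samples",
    "synthetic_observer",
]

TEXTURE_KINDS = ("onef_noise", "plaid_3.5cpd", "plaid_5.25cpd")

_PLAID_CPD = {"plaid_3.5cpd": 3.5, "plaid_5.25cpd": 5.25}


class UnknownTextureError(ValueError):
    pass


@dataclass(frozen=True)
class ViewingGeometry:
    """Stereo viewing geometry. Defaults: adult IPD, 1920 px over 36 deg."""

    interocular_distance: float = 0.065  # meters
    view_distance_screen: float = 3.0  # meters (display metadata only)
    pixels_per_degree: float = 1920.0 / 36.0
    image_size: int = 64  # px (square patches)

    def __post_init__(self):
        for name in ("interocular_distance", "view_distance_screen", "pixels_per_degree", "image_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def focal_px(self) -> float:
        """Pixels per radian of the tangent-plane projection."""
        return self.pixels_per_degree * 180.0 / math.pi


@dataclass(frozen=True)
class SceneSpec:
    """One synthetic scene: a textured plane plus optional bump field."""

    tilt: float = 90.0  # degrees in [0, 360)
    slant: float = 45.0  # degrees in [0, 90)
    distance: float = 10.0  # meters to the patch center
    texture_kind: str = "plaid_3.5cpd"
    bump_amplitude: float = 0.0  # meters RMS, along the surface normal
    bump_corr_length: float = 0.5  # degrees of visual angle
    seed: int = 0
    contrast: float = 0.2  # target windowed RMS contrast
    mean_luminance: float = 100.0  # linear arbitrary units
    shading_gamma: float = 3.0  # luminance falls off as (d/r)^gamma

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if not 0.0 <= self.slant < 90.0:
            raise ValueError("slant must be in [0, 90)")
        if self.bump_amplitude < 0:
            raise ValueError("bump_amplitude must be >= 0")
        if self.texture_kind not in TEXTURE_KINDS:
            raise UnknownTextureError(f"unknown texture kind: {self.texture_kind!r}")


@dataclass
class StereoPatch:
    """Left/right luminance images plus cyclopean range map and metadata."""

    left_image: np.ndarray
    right_image: np.ndarray
    range_map: np.ndarray  # meters from the cyclopean eye
    spec: SceneSpec
    occlusion_mask: np.ndarray  # True where not binocularly visible
    geom: ViewingGeometry
    achieved_contrast: float = float("nan")
    stimulus_id: str = ""

    def __post_init__(self):
        if not (self.left_image.shape == self.right_image.shape == self.range_map.shape):
            raise ValueError("patch arrays must share dimensions")


@dataclass(frozen=True)
class SamplingConstraints:
    """Experiment stimulus-sampling constraints."""

    min_slant: float = 30.0  # degrees, strict lower bound
    distance_range: tuple[float, float] = (5.0, 50.0)  # meters
    contrast_range: tuple[float, float] = (0.05, 0.40)
    n_tilt_bins: int = 24
    n_per_bin: int = 150
    max_slant: float = 70.0


@dataclass(frozen=True)
class SyntheticObserverSpec:
    """Response model: model estimate + per-tilt bias + axial noise + lapses."""

    noise_concentration: float = 10.0  # von-Mises kappa on doubled angles
    lapse_rate: float = 0.0
    bias_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.noise_concentration < 0:
            raise ValueError("noise_concentration must be >= 0")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# textures


def make_texture(kind: str, size: int, pixels_per_degree: float, seed=None) -> np.ndarray:
    """Zero-mean, unit-RMS texture of the given kind.

    ``onef_noise`` has amplitude spectrum proportional to 1/f; the plaid
    kinds are sums of two gratings at the labelled spatial frequency with
    independently randomized orientations and phases. ``seed`` may be an int
    or a ``numpy.random.Generator``.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if kind not in TEXTURE_KINDS:
        raise UnknownTextureError(f"unknown texture kind: {kind!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind == "onef_noise":
        fy = np.fft.fftfreq(size)[:, None]
        fx = np.fft.fftfreq(size)[None, :]
        f = np.hypot(fx, fy)
        f[0, 0] = np.inf  # kill DC
        spectrum = np.fft.fft2(rng.standard_normal((size, size))) / f
        tex = np.real(np.fft.ifft2(spectrum))
    else:
        cyc_per_px = _PLAID_CPD[kind] / pixels_per_degree
        y, x = np.indices((size, size), dtype=float)
        y = -y  # y-up
        tex = np.zeros((size, size))
        for _ in range(2):
            theta = rng.uniform(0.0, 180.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            carrier = np.cos(theta * np.pi / 180.0) * x + np.sin(theta * np.pi / 180.0) * y
            tex += np.cos(2.0 * np.pi * cyc_per_px * carrier + phase)
    tex -= tex.mean()
    rms = tex.std()
    if rms > 0:
        tex /= rms
    return tex


# ---------------------------------------------------------------------------
# rendering


def _plane_frame(tilt_deg: float, slant_deg: float):
    t = math.radians(tilt_deg)
    s = math.radians(slant_deg)
    n = np.array([-math.sin(s) * math.cos(t), -math.sin(s) * math.sin(t), math.cos(s)])
    e1 = np.array([-math.sin(t), math.cos(t), 0.0])
    e2 = np.cross(n, e1)
    return n, e1, e2


def _texture_grid(spec: SceneSpec, geom: ViewingGeometry) -> tuple[float, int]:
    """Meters-per-texel and texel count for the surface texture grid."""
    rad_per_px = 1.0 / geom.focal_px
    t_m = 0.5 * spec.distance * rad_per_px  # 2x oversampled vs image pixels
    corner = (geom.image_size / 2.0 + 2.0) * math.sqrt(2.0) * rad_per_px
    s = math.radians(spec.slant)
    denom = max(math.cos(s) * (1.0 - corner * math.tan(s)), 0.05)
    half_extent = 1.4 * spec.distance * corner / denom
    half_extent += geom.interocular_distance + 4.0 * spec.bump_amplitude
    n_tex = int(math.ceil(2.0 * half_extent / t_m))
    n_tex = int(np.clip(n_tex, 64, 1024))
    return t_m, n_tex + (n_tex % 2)


def perturb_surface(
    spec: SceneSpec,
    geom: ViewingGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray | None, float]:
    """Smooth random height field (meters, along the surface normal).

    Gaussian-correlated noise synthesized in the frequency domain with
    correlation length ``spec.bump_corr_length`` (degrees, converted to
    meters at the patch distance). The field is scaled analytically so that
    an infinite surface would have RMS height ``spec.bump_amplitude``; when
    the correlation length far exceeds the rendered footprint the realized
    field is nearly constant and the patch is locally planar. Returns
    ``(height_field, meters_per_texel)``; the field is None for amplitude 0,
    in which case rendering is exactly planar.
    """
    geom = geom or ViewingGeometry()
    t_m, n_tex = _texture_grid(spec, geom)
    if spec.bump_amplitude == 0.0:
        return None, t_m
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    corr_m = spec.distance * math.tan(math.radians(spec.bump_corr_length))
    sigma_texel = max(corr_m / t_m, 0.5)
    f = np.fft.fftfreq(n_tex)
    f2 = f[:, None] ** 2 + f[None, :] ** 2
    transfer = np.exp(-2.0 * np.pi**2 * sigma_texel**2 * f2)
    transfer[0, 0] = 0.0  # mean-zero height field
    noise = rng.standard_normal((n_tex, n_tex))
    h = np.real(np.fft.ifft2(np.fft.fft2(noise) * transfer))
    # continuum variance of unit white noise under this filter is 1/(4 pi sigma^2)
    h *= spec.bump_amplitude * 2.0 * math.sqrt(math.pi) * sigma_texel
    return h, t_m


def _bilinear(grid: np.ndarray, q_col: np.ndarray, q_row: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(
        grid, [q_row, q_col], order=1, mode="constant", cval=np.nan, prefilter=False
    )


def render_stereo(
    spec: SceneSpec,
    geom: ViewingGeometry | None = None,
    convergence_distance: float | str | None = "auto",
) -> StereoPatch:
    """Render a stereo patch (left/right images + cyclopean range map).

    Inverse ray casting per pixel with bilinear texture lookup. The texture
    is painted on the surface at a physical scale chosen so its nominal
    spatial frequency (cycles/deg) is realized at the patch center; slant
    then foreshortens it exactly as perspective dictates. Luminance is
    ``mean_luminance * (d/r)^shading_gamma * (1 + a*texture)`` with the
    modulation amplitude calibrated to the target contrast of the left
    image. ``convergence_distance="auto"`` converges the eyes at the patch
    center (disparity ~0 there); None or inf gives parallel viewing axes
    (absolute disparity ``b/z`` radians).

    Deterministic: identical spec + geometry give bit-identical patches.
    """
    geom = geom or ViewingGeometry()
    if spec.slant >= 90.0 or spec.distance <= 0:
        raise ValueError("surface must be in front of the viewer with slant < 90 deg")
    if convergence_distance == "auto":
        dc = spec.distance
    elif convergence_distance is None:
        dc = math.inf
    else:
        dc = float(convergence_distance)

    rng = np.random.default_rng(spec.seed)
    t_m, n_tex = _texture_grid(spec, geom)
    # effective sampling rate of the texture grid in "pixels per degree"
    ppd_tex = (spec.distance * math.pi / 180.0) / t_m
    texture = make_texture(spec.texture_kind, n_tex, ppd_tex, rng)
    height, _ = perturb_surface(spec, geom, rng)

    n, e1, e2 = _plane_frame(spec.tilt, spec.slant)
    p0 = np.array([0.0, 0.0, spec.distance])
    size = geom.image_size
    f_px = geom.focal_px
    c = (size - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float))
    x_img = (cols - c) / f_px
    y_img = (c - rows) / f_px  # y-up

    b = geom.interocular_distance
    eyes = {"left": -b / 2.0, "right": b / 2.0, "cyclopean": 0.0}
    tex_center = (n_tex - 1) / 2.0

    def cast(eye_x: float):
        E = np.array([eye_x, 0.0, 0.0])
        shift = 0.0 if math.isinf(dc) else eye_x / dc
        u = np.stack([x_img - shift, y_img, np.ones_like(x_img)], axis=-1)
        denom = u @ n
        t = float(n @ (p0 - E)) / denom
        if height is not None:
            for _ in range(12):
                P = E + t[..., None] * u
                rel = P - p0
                q1 = (rel @ e1) / t_m + tex_center
                q2 = (rel @ e2) / t_m + tex_center
                h = _bilinear(height, q1, q2)
                h = np.nan_to_num(h, nan=0.0)
                resid = rel @ n - h
                t = t - resid / denom
        P = E + t[..., None] * u
        rel = P - p0
        q1 = (rel @ e1) / t_m + tex_center
        q2 = (rel @ e2) / t_m + tex_center
        tex_val = _bilinear(texture, q1, q2)
        r_cyc = np.linalg.norm(P, axis=-1)  # shading is eye-independent
        dist = t * np.linalg.norm(u, axis=-1)
        valid = (t > 0) & np.isfinite(tex_val)
        return tex_val, r_cyc, dist, valid

    tex_l, rcyc_l, _, ok_l = cast(eyes["left"])
    tex_r, rcyc_r, _, ok_r = cast(eyes["right"])
    _, _, range_map, ok_c = cast(eyes["cyclopean"])
    occlusion = ~(ok_l & ok_r & ok_c)
    if occlusion[size // 2, size // 2]:
        raise ValueError("surface not visible at patch center from both eyes")

    shade_l = spec.mean_luminance * (spec.distance / rcyc_l) ** spec.shading_gamma
    shade_r = spec.mean_luminance * (spec.distance / rcyc_r) ** spec.shading_gamma
    tex_l = np.nan_to_num(tex_l, nan=0.0)
    tex_r = np.nan_to_num(tex_r, nan=0.0)

    cue_cfg = image_cues.CueConfig(pixels_per_degree=geom.pixels_per_degree)
    amp = spec.contrast
    achieved = float("nan")
    for _ in range(3):
        left = shade_l * (1.0 + amp * tex_l)
        achieved = image_cues.local_contrast(np.maximum(left, 1e-9), cue_cfg)
        if achieved <= 0:
            break
        if abs(achieved - spec.contrast) < 1e-4 * spec.contrast:
            break
        amp *= spec.contrast / achieved
    left = shade_l * (1.0 + amp * tex_l)
    right = shade_r * (1.0 + amp * tex_r)
    achieved = image_cues.local_contrast(np.maximum(left, 1e-9), cue_cfg)

    return StereoPatch(
        left_image=left,
        right_image=right,
        range_map=np.where(ok_c, range_map, spec.distance),
        spec=spec,
        occlusion_mask=occlusion,
        geom=geom,
        achieved_contrast=achieved,
    )


# ---------------------------------------------------------------------------
# stimulus sampling


def _center_truth(patch: StereoPatch) -> tuple[float, float]:
    """Recomputed (signed tilt, slant) at the patch center from the range map."""
    cfg = surface_truth.TruthConfig(pixels_per_degree=patch.geom.pixels_per_degree)
    dx, dy = surface_truth.range_gradient(patch.range_map, cfg)
    tm = surface_truth.groundtruth_tilt(dx, dy)
    cy, cx = patch.range_map.shape[0] // 2, patch.range_map.shape[1] // 2
    slant = surface_truth.groundtruth_slant(patch.range_map, cfg)[cy, cx]
    return float(tm.signed_tilt[cy, cx]), float(slant)


def sample_stimuli(
    constraints: SamplingConstraints | None = None,
    geom: ViewingGeometry | None = None,
    seed: int = 0,
    texture_kinds: Sequence[str] = TEXTURE_KINDS,
    bump_amplitude_range: tuple[float, float] = (0.0, 0.0),
    bump_corr_length: float = 0.5,
) -> list[StereoPatch]:
    """Constrained random sampling of experiment stimuli.

    Returns exactly ``n_tilt_bins * n_per_bin`` patches. Tilt bins partition
    [0, 360); within each bin, tilt, slant, distance, contrast (and bump
    amplitude, if a range is given) are drawn at random, the patch rendered,
    and the constraints re-checked on the rendered patch (recomputed center
    tilt in its assigned bin, slant above the minimum, distance and contrast
    in range, no half-occlusion at the center). Rejection sampling; the
    per-bin acceptance rates are recorded on the returned list's
    ``.acceptance_rates`` attribute via ``sample_stimuli.last_acceptance``.
    Aborts if any bin's acceptance rate drops below 0.1%.
    """
    constraints = constraints or SamplingConstraints()
    geom = geom or ViewingGeometry()
    if constraints.n_per_bin < 1:
        raise ValueError("n_per_bin must be >= 1")
    rng = np.random.default_rng(seed)
    bin_width = 360.0 / constraints.n_tilt_bins
    d_lo, d_hi = constraints.distance_range
    c_lo, c_hi = constraints.contrast_range
    patches: list[StereoPatch] = []
    acceptance: dict[int, float] = {}
    for b in range(constraints.n_tilt_bins):
        accepted = 0
        attempts = 0
        while accepted < constraints.n_per_bin:
            attempts += 1
            if attempts >= 1000 and accepted / attempts < 0.001:
                raise RuntimeError(
                    f"tilt bin {b}: acceptance rate {accepted / attempts:.5f} < 0.1% "
                    f"after {attempts} attempts"
                )
            spec = SceneSpec(
                tilt=(b + rng.uniform(0.02, 0.98)) * bin_width,
                slant=rng.uniform(constraints.min_slant + 1.0, constraints.max_slant),
                distance=float(np.exp(rng.uniform(np.log(d_lo * 1.02), np.log(d_hi * 0.98)))),
                texture_kind=str(rng.choice(list(texture_kinds))),
                bump_amplitude=float(rng.uniform(*bump_amplitude_range)),
                bump_corr_length=bump_corr_length,
                contrast=float(rng.uniform(c_lo + 0.01, c_hi - 0.01)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            try:
                patch = render_stereo(spec, geom)
            except ValueError:
                continue
            tilt_hat, slant_hat = _center_truth(patch)
            if not b * bin_width <= tilt_hat < (b + 1) * bin_width:
                continue
            if not slant_hat > constraints.min_slant:
                continue
            if not d_lo <= spec.distance <= d_hi:
                continue
            if not c_lo <= patch.achieved_contrast <= c_hi:
                continue
            half = geom.image_size // 4
            cy = geom.image_size // 2
            if patch.occlusion_mask[cy - half : cy + half, cy - half : cy + half].any():
                continue
            patch.stimulus_id = f"bin{b:02d}_n{accepted:04d}_s{spec.seed}"
            patches.append(patch)
            accepted += 1
        acceptance[b] = accepted / attempts
    sample_stimuli.last_acceptance = acceptance
    return patches


sample_stimuli.last_acceptance = {}


def sample_tilt_prior(
    n: int,
    seed: int = 0,
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
    concentration: float = 16.0,
) -> np.ndarray:
    """Unsigned tilts from a cardinal-heavy mixture prior.

    Mixture of ground-plane-like tilts (around 90 deg), trunk-like tilts
    (around 0/180 deg) and a uniform oblique component, with axial von-Mises
    spread. Qualitatively reproduces the cardinal-dominated shape of the
    natural tilt prior.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(3, size=n, p=w)
    tilts = np.empty(n)
    noise = np.degrees(rng.vonmises(0.0, concentration, size=n)) / 2.0
    tilts[comp == 0] = 90.0 + noise[comp == 0]
    tilts[comp == 1] = 0.0 + noise[comp == 1]
    tilts[comp == 2] = rng.uniform(0.0, 180.0, size=(comp == 2).sum())
    return tilts % 180.0


def simulate_cue_samples(
    tilts: np.ndarray,
    kappas: float | Sequence[float] = 8.0,
    seed: int = 0,
    unreliable_value: float = float("nan"),
) -> np.ndarray:
    """Fast synthetic cue triplets: tilt plus independent axial noise per cue.

    Emulates the statistics of the rendered cues (each cue is an unbiased
    but noisy measurement of unsigned tilt) without the cost of rendering;
    used to train estimate cubes at scale. ``kappas`` is the von-Mises
    concentration on doubled angles, per cue or shared. Returns an (n, 3)
    array of cues in [0, 180).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(tilts, dtype=float)
    kap = np.broadcast_to(np.asarray(kappas, dtype=float), (3,))
    cues = np.empty((t.size, 3))
    for j in range(3):
        if np.isinf(kap[j]):
            noise = np.zeros(t.size)
        elif kap[j] <= 1e-12:
            noise = rng.uniform(-90.0, 90.0, size=t.size)
        else:
            noise = np.degrees(rng.vonmises(0.0, kap[j], size=t.size)) / 2.0
        cues[:, j] = (t + noise) % 180.0
    return cues


def simulate_natural_cue_samples(
    tilts: np.ndarray,
    seed: int = 0,
    kappa_range: tuple[float, float] = (0.5, 64.0),
    baseline_obliqueness: float = 0.25,
) -> np.ndarray:
    """Cue triplets with tilt-dependent reliability, emulating natural scenes.

    In natural scenes cue reliability co-varies with tilt: surfaces at
    cardinal tilts (ground planes, trunks) tend to be planar and yield
    reliable cues, while oblique tilts tend to occur on bumpy regions with
    unreliable cues. Each trial draws a von-Mises concentration whose
    log is uniform between the top of ``kappa_range`` and a tilt-dependent
    floor that decreases with obliqueness; all three cues share the trial's
    reliability. Returns an (n, 3) array of cues in [0, 180).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(tilts, dtype=float) % 180.0
    d_card = np.minimum(
        np.abs(circ_error(t, 0.0, period=180.0)), np.abs(circ_error(t, 90.0, period=180.0))
    )
    obliqueness = baseline_obliqueness + (1.0 - baseline_obliqueness) * d_card / 45.0
    k_lo, k_hi = kappa_range
    log_span = (np.log(k_hi) - np.log(k_lo)) * obliqueness * rng.random(t.size)
    kappa = np.exp(np.log(k_hi) - log_span)
    cues = np.empty((t.size, 3))
    for j in range(3):
        noise = np.degrees(rng.vonmises(0.0, kappa, size=t.size)) / 2.0
        cues[:, j] = (t + noise) % 180.0
    return cues


def sample_database_patches(
    n: int,
    geom: ViewingGeometry | None = None,
    seed: int = 0,
    prior_weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
    slant_range: tuple[float, float] = (30.0, 70.0),
    distance_range: tuple[float, float] = (5.0, 50.0),
    contrast_range: tuple[float, float] = (0.06, 0.39),
    bump_amplitude_range: tuple[float, float] = (0.0, 0.0),
    texture_kinds: Sequence[str] = TEXTURE_KINDS,
) -> list[StereoPatch]:
    """Render n patches with tilts drawn from the cardinal-heavy prior.

    Emulates sampling from a natural-scene database (for cube training),
    as opposed to the uniform-per-tilt-bin experiment sampler.
    """
    geom = geom or ViewingGeometry()
    rng = np.random.default_rng(seed)
    tilts_unsigned = sample_tilt_prior(n, seed=int(rng.integers(2**31)), weights=prior_weights)
    signs = rng.choice([0.0, 180.0], size=n)
    patches = []
    for i in range(n):
        spec = SceneSpec(
            tilt=float((tilts_unsigned[i] + signs[i]) % 360.0),
            slant=float(rng.uniform(*slant_range)),
            distance=float(np.exp(rng.uniform(*np.log(distance_range)))),
            texture_kind=str(rng.choice(list(texture_kinds))),
            bump_amplitude=float(rng.uniform(*bump_amplitude_range)),
            contrast=float(rng.uniform(*contrast_range)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        patch = render_stereo(spec, geom)
        patch.stimulus_id = f"db_{i:06d}"
        patches.append(patch)
    return patches


def synthetic_observer(
    estimates,
    obs: SyntheticObserverSpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Emulated human responses to a sequence of model estimates (deg, [0,180)).

    Each response is estimate + bias_fn(estimate) + axial von-Mises noise
    (sampled on doubled angles and halved); with probability ``lapse_rate``
    the response is instead uniform on [0, 180).
    """
    obs = obs or SyntheticObserverSpec()
    est = np.asarray(estimates, dtype=float)
    rng = np.random.default_rng(seed)
    out = est.copy()
    if obs.bias_fn is not None:
        out = out + np.asarray(obs.bias_fn(est), dtype=float)
    kappa = obs.noise_concentration
    if np.isinf(kappa):
        noise = np.zeros(est.shape)
    elif kappa <= 1e-12:
        noise = rng.uniform(-90.0, 90.0, size=est.shape)
    else:
        noise = np.degrees(rng.vonmises(0.0, kappa, size=est.shape)) / 2.0
    out = (out + noise) % 180.0
    if obs.lapse_rate > 0:
        lapse = rng.random(est.shape) < obs.lapse_rate
        out = np.where(lapse, rng.uniform(0.0, 180.0, size=est.shape), out)
    return out
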