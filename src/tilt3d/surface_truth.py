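"""Groundtruth surface orientation from range maps.

Tilt is the orientation of the local range gradient: the range map is
smoothed with a Gaussian kernel and differentiated, and tilt is
``atan2(dr/dy, dr/dx)``. The image convention is y-up (row 0 at the top of
the array, elevation increasing upward), so a ground-plane-like patch whose
range increases with elevation has tilt 90 deg and a vertical-trunk-like
patch has tilt 0/180 deg. Slant is the angle between the local surface
normal and the line of sight, reconstructed from the angular range gradient
and the local range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .circstats import circ_mean_var

__all__ = [
    "TruthConfig",
    "TiltMap",
    "range_gradient",
    "groundtruth_tilt",
    "to_unsigned",
    "tilt_variance",
    "groundtruth_slant",
    "central_mask",
]

#: gradient magnitude (m/px) below which tilt is considered undefined
GRADIENT_EPS = 1e-6


@dataclass(frozen=True)
class TruthConfig:
    sigma_truth_arcmin: float = 3.0
    pixels_per_degree: float = 1920.0 / 36.0
    central_region_diameter_deg: float = 1.0

    def __post_init__(self):
        if self.sigma_truth_arcmin <= 0:
            raise ValueError("sigma_truth_arcmin must be positive")
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")

    @property
    def sigma_px(self) -> float:
        return self.sigma_truth_arcmin / 60.0 * self.pixels_per_degree


@dataclass
class TiltMap:
    signed_tilt: np.ndarray  # degrees in [0, 360) per pixel
    gradient_magnitude: np.ndarray  # meters/pixel
    defined_mask: np.ndarray  # False where the gradient is ~zero


def range_gradient(range_map: np.ndarray, cfg: TruthConfig | None = None):
    """Gaussian-derivative gradient (dx, dy) of a range map, y-up convention.

    The map is convolved with a 2D Gaussian of space constant
    ``cfg.sigma_truth_arcmin`` (converted to pixels) and differentiated.
    Returns meters-per-pixel partials; ``dy`` is positive where range
    increases with image elevation.
    """
    cfg = cfg or TruthConfig()
    r = np.asarray(range_map, dtype=float)
    if r.ndim != 2:
        raise ValueError("range_map must be 2D")
    if not np.all(np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("range_map must be finite and positive")
    sigma = cfg.sigma_px
    if sigma < 0.5:
        warnings.warn(
            f"range-gradient kernel under-resolved (sigma={sigma:.3f} px)",
            RuntimeWarning,
            stacklevel=2,
        )
    # axis 0 is image row (top to bottom), axis 1 is x
    dx = ndimage.gaussian_filter(r, sigma, order=(0, 1), mode="reflect", truncate=3.0)
    d_row = ndimage.gaussian_filter(r, sigma, order=(1, 0), mode="reflect", truncate=3.0)
    dy = -d_row  # y-up
    return dx, dy


def groundtruth_tilt(dx: np.ndarray, dy: np.ndarray) -> TiltMap:
    """Signed tilt map (orientation of the range gradient) from partials."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if dx.shape != dy.shape:
        raise ValueError("gradient components must be co-registered")
    signed = np.degrees(np.arctan2(dy, dx)) % 360.0
    mag = np.hypot(dx, dy)
    return TiltMap(signed_tilt=signed, gradient_magnitude=mag, defined_mask=mag >= GRADIENT_EPS)


def to_unsigned(angle_deg):
    """Angle modulo 180: maps signed tilt [0,360) to unsigned tilt [0,180)."""
    a = np.asarray(angle_deg, dtype=float)
    out = a % 180.0
    # tiny negative inputs can round to exactly 180.0 after the modulo
    out = np.where(out >= 180.0, 0.0, out)
    if np.ndim(angle_deg) == 0:
        return float(out)
    return out


def central_mask(shape: tuple[int, int], diameter_px: float) -> np.ndarray:
    """Boolean mask of the centered circular region of the given diameter."""
    rows, cols = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    return (rows - cy) ** 2 + (cols - cx) ** 2 <= (diameter_px / 2.0) ** 2


def tilt_variance(tilt_map: TiltMap, cfg: TruthConfig | None = None) -> float:
    """Circular variance of unsigned tilt in the central region of the map.

    Computed on the defined pixels inside a centered disk of diameter
    ``cfg.central_region_diameter_deg``. 0 for a planar patch; approaches 1
    for uniformly distributed tilts.
    """
    cfg = cfg or TruthConfig()
    diam_px = cfg.central_region_diameter_deg * cfg.pixels_per_degree
    region = central_mask(tilt_map.signed_tilt.shape, diam_px) & tilt_map.defined_mask
    if region.sum() < 2:
        raise ValueError("tilt variance undefined: fewer than 2 defined central pixels")
    tilts = to_unsigned(tilt_map.signed_tilt[region])
    return circ_mean_var(tilts, period=180.0).variance


def groundtruth_slant(
    range_map: np.ndarray,
    cfg: TruthConfig | None = None,
    pixels_per_degree: float | None = None,
) -> np.ndarray:
    """Per-pixel slant (deg): angle between surface normal and line of sight.

    Reconstructed from the angular range gradient: a plane at range r whose
    range changes by ``g`` meters per radian of visual angle has slant
    ``atan(|g| / r)``. Matches the construction slant of rendered planes to
    within discretization error.
    """
    cfg = cfg or TruthConfig()
    ppd = pixels_per_degree if pixels_per_degree is not None else cfg.pixels_per_degree
    dx, dy = range_gradient(range_map, cfg)
    px_per_rad = ppd * 180.0 / np.pi
    grad_per_rad = np.hypot(dx, dy) * px_per_rad
    return np.degrees(np.arctan2(grad_per_rad, np.asarray(range_map, dtype=float)))
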