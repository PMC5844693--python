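"""Circular statistics for angular and axial (period-180) data.

Surface tilt is an angular variable; unsigned tilt lives on a half-circle
(period 180 deg). All functions take a ``period`` argument: angles are
mapped onto the full circle by scaling with ``360 / period``, statistics
are computed on the unit circle, and results are mapped back. With
``period=180`` this is the standard doubled-angle treatment of axial data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CircularSummary",
    "circ_mean_var",
    "circ_error",
    "circ_corr",
    "bootstrap_ci",
]

#: below this resultant length the circular mean is numerically undefined
_RESULTANT_EPS = 1e-9


@dataclass(frozen=True)
class CircularSummary:
    """Summary of a set of angles on a circle of the given period."""

    resultant: complex  # mean resultant vector on the scaled circle
    mean: float  # degrees in [0, period); NaN when undefined
    variance: float  # 1 - |resultant|, in [0, 1]
    n: int
    period: float
    mean_defined: bool


def _to_phase(angles_deg: np.ndarray, period: float) -> np.ndarray:
    return np.deg2rad(np.asarray(angles_deg, dtype=float) * (360.0 / period))


def circ_mean_var(angles_deg, period: float = 360.0) -> CircularSummary:
    """Circular mean and variance of ``angles_deg`` on a circle of ``period``.

    The mean is ``arg(R)`` and the variance ``1 - |R|`` where ``R`` is the
    complex mean resultant vector of the (scaled) angles. When ``|R|`` is
    numerically zero the mean is undefined and returned as NaN with
    ``mean_defined=False``; the variance is still valid (== 1).
    """
    a = np.asarray(angles_deg, dtype=float).ravel()
    if a.size < 1:
        raise ValueError("circ_mean_var requires at least one angle")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    resultant = complex(np.exp(1j * _to_phase(a, period)).mean())
    r_len = abs(resultant)
    variance = float(min(max(1.0 - r_len, 0.0), 1.0))
    defined = r_len >= _RESULTANT_EPS
    if defined:
        mean = float(np.rad2deg(np.angle(resultant)) * (period / 360.0) % period)
    else:
        mean = float("nan")
    return CircularSummary(
        resultant=resultant,
        mean=mean,
        variance=variance,
        n=int(a.size),
        period=float(period),
        mean_defined=bool(defined),
    )


def circ_error(estimate_deg, truth_deg, period: float = 360.0):
    """Signed circular distance estimate - truth, wrapped to (-period/2, period/2].

    Antisymmetric except exactly at the boundary, where the sign is fixed
    to ``+period/2`` for determinism. Works elementwise on arrays.
    """
    est = np.asarray(estimate_deg, dtype=float)
    tru = np.asarray(truth_deg, dtype=float)
    d = (est - tru) % period
    d = np.where(d > period / 2.0, d - period, d)
    # map the -period/2 representation of the boundary onto +period/2
    d = np.where(np.isclose(d, -period / 2.0), period / 2.0, d)
    if np.ndim(estimate_deg) == 0 and np.ndim(truth_deg) == 0:
        return float(d)
    return d


def circ_corr(a_deg, b_deg, period: float = 360.0) -> float:
    """Fisher-Lee circular correlation coefficient between two angle sequences.

    Computed with the O(n) expansion of the pairwise definition

        r = sum_{i<j} sin(ai-aj) sin(bi-bj)
            / sqrt(sum_{i<j} sin^2(ai-aj) * sum_{i<j} sin^2(bi-bj)).

    Returns NaN when either sequence is (circularly) constant.
    """
    a = _to_phase(np.asarray(a_deg, dtype=float).ravel(), period)
    b = _to_phase(np.asarray(b_deg, dtype=float).ravel(), period)
    if a.size != b.size:
        raise ValueError("sequences must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    n = a.size
    sa, ca = np.sin(a), np.cos(a)
    sb, cb = np.sin(b), np.cos(b)
    num = (sa @ sb) * (ca @ cb) - (sa @ cb) * (ca @ sb)
    # sum over ordered pairs of sin^2(ai - aj) = (n^2 - |sum exp(2i a)|^2) / 2
    denom_a = (n * n - abs(np.exp(2j * a).sum()) ** 2) / 2.0
    denom_b = (n * n - abs(np.exp(2j * b).sum()) ** 2) / 2.0
    if denom_a <= 1e-12 * n * n or denom_b <= 1e-12 * n * n:
        return float("nan")
    return float(2.0 * num / np.sqrt(denom_a * denom_b))


def bootstrap_ci(
    statistic_fn: Callable[..., float],
    data: Sequence | tuple,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for ``statistic_fn(data)``.

    ``data`` may be a single array or a tuple of equal-length arrays that are
    resampled jointly (paired bootstrap). Degenerate resamples for which the
    statistic is NaN are skipped; their count is recorded on the function
    attribute ``bootstrap_ci.last_n_skipped``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if isinstance(data, tuple):
        arrays = [np.asarray(d) for d in data]
        n = arrays[0].shape[0]
        if any(arr.shape[0] != n for arr in arrays):
            raise ValueError("paired arrays must share length")
    else:
        arrays = [np.asarray(data)]
        n = arrays[0].shape[0]
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    skipped = 0
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        val = statistic_fn(*(arr[idx] for arr in arrays))
        stats[i] = val
    ok = np.isfinite(stats)
    skipped = int(n_boot - ok.sum())
    bootstrap_ci.last_n_skipped = skipped
    if skipped == n_boot:
        raise ValueError("all bootstrap resamples were degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats[ok], [alpha, 1.0 - alpha])
    return float(lo), float(hi)


bootstrap_ci.last_n_skipped = 0
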