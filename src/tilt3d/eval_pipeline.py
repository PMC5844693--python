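"""Psychophysics-style evaluation of tilt estimates.

Works on trial tables (pandas DataFrames) with one row per stimulus
presentation. All angular quantities are unsigned tilt in degrees [0, 180);
errors are signed circular differences in (-90, 90]. Analyses: per-tilt
summary statistics, conditional error / conditional-truth distributions,
bias correction, trial-by-trial circular correlation with bootstrap CIs,
variance explained, covariate effects (slant, distance, tilt variance) and
Monte Carlo experiment repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .circstats import bootstrap_ci, circ_corr, circ_error, circ_mean_var

__all__ = [
    "TRIAL_COLUMNS",
    "BinnedSummary",
    "make_trials",
    "summarize_by_tilt",
    "conditional_error_dist",
    "conditional_truth_dist",
    "bias_correct",
    "trial_corr",
    "variance_explained",
    "covariate_effect",
    "cardinal_oblique_split",
    "monte_carlo_experiment",
]

TRIAL_COLUMNS = [
    "stimulus_id",
    "truth_tilt",
    "estimate",
    "error",
    "slant",
    "distance",
    "contrast",
    "tilt_variance",
    "observer_id",
]


def make_trials(
    truth_tilt,
    estimate,
    stimulus_id=None,
    slant=np.nan,
    distance=np.nan,
    contrast=np.nan,
    tilt_variance=np.nan,
    observer_id="model",
) -> pd.DataFrame:
    """Assemble a trial table; error is computed as circ_error(estimate, truth)."""
    truth = np.asarray(truth_tilt, dtype=float) % 180.0
    est = np.asarray(estimate, dtype=float) % 180.0
    n = truth.size
    if stimulus_id is None:
        stimulus_id = np.arange(n)
    return pd.DataFrame(
        {
            "stimulus_id": stimulus_id,
            "truth_tilt": truth,
            "estimate": est,
            "error": circ_error(est, truth, period=180.0),
            "slant": np.broadcast_to(np.asarray(slant, dtype=float), (n,)),
            "distance": np.broadcast_to(np.asarray(distance, dtype=float), (n,)),
            "contrast": np.broadcast_to(np.asarray(contrast, dtype=float), (n,)),
            "tilt_variance": np.broadcast_to(np.asarray(tilt_variance, dtype=float), (n,)),
            "observer_id": observer_id,
        }
    )


def _tilt_bin_index(angles: np.ndarray, n_bins: int, domain: float) -> np.ndarray:
    width = domain / n_bins
    return np.clip(np.floor((np.asarray(angles, dtype=float) % domain) / width).astype(int), 0, n_bins - 1)


@dataclass
class BinnedSummary:
    """Per-truth-tilt-bin summary statistics of the estimates."""

    bin_centers: np.ndarray  # degrees
    n_presented: np.ndarray  # trials per truth bin
    n_estimated: np.ndarray  # estimates falling in each bin
    mean: np.ndarray  # circular mean of estimates per truth bin (NaN if empty/undefined)
    variance: np.ndarray  # circular variance of estimates per truth bin
    count_ratio: np.ndarray  # n_estimated / n_presented

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size


def summarize_by_tilt(trials: pd.DataFrame, n_bins: int = 24, domain: float = 180.0) -> BinnedSummary:
    """Estimate counts, circular means and circular variances per truth-tilt bin."""
    if len(trials) < 1:
        raise ValueError("no trials")
    width = domain / n_bins
    centers = (np.arange(n_bins) + 0.5) * width
    tb = _tilt_bin_index(trials["truth_tilt"].to_numpy(), n_bins, domain)
    eb = _tilt_bin_index(trials["estimate"].to_numpy(), n_bins, domain)
    n_presented = np.bincount(tb, minlength=n_bins)
    n_estimated = np.bincount(eb, minlength=n_bins)
    mean = np.full(n_bins, np.nan)
    variance = np.full(n_bins, np.nan)
    est = trials["estimate"].to_numpy()
    for b in range(n_bins):
        sel = tb == b
        if not sel.any():
            continue
        s = circ_mean_var(est[sel], period=domain)
        mean[b] = s.mean
        variance[b] = s.variance
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_presented > 0, n_estimated / np.maximum(n_presented, 1), np.nan)
    return BinnedSummary(centers, n_presented, n_estimated, mean, variance, ratio)


def _normalized_hist(values: np.ndarray, n_bins: int, lo: float, hi: float):
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / counts.sum()


def conditional_error_dist(
    trials: pd.DataFrame, truth_bin: int, n_truth_bins: int = 24, n_error_bins: int = 24
):
    """Normalized histogram of errors p(e | truth bin). Returns (centers, probs)."""
    tb = _tilt_bin_index(trials["truth_tilt"].to_numpy(), n_truth_bins, 180.0)
    sel = tb == truth_bin
    if not sel.any():
        raise ValueError(f"truth bin {truth_bin} is empty")
    return _normalized_hist(trials["error"].to_numpy()[sel], n_error_bins, -90.0, 90.0)


def conditional_truth_dist(
    trials: pd.DataFrame, estimate_bin: int, n_bins: int = 24
):
    """Normalized histogram of truth tilts p(tau | estimate bin)."""
    eb = _tilt_bin_index(trials["estimate"].to_numpy(), n_bins, 180.0)
    sel = eb == estimate_bin
    if not sel.any():
        raise ValueError(f"estimate bin {estimate_bin} is empty")
    return _normalized_hist(trials["truth_tilt"].to_numpy()[sel], n_bins, 0.0, 180.0)


def bias_correct(trials: pd.DataFrame, n_bins: int = 24) -> pd.DataFrame:
    """Subtract the per-truth-bin circular mean error (the observer bias).

    Adds an ``error_bc`` column: e* = error - E[error | truth bin], computed
    with period-180 circular arithmetic and re-wrapped into (-90, 90]. The
    per-bin circular mean of e* is zero by construction. Bins with fewer
    than 2 trials get bias 0.
    """
    out = trials.copy()
    tb = _tilt_bin_index(out["truth_tilt"].to_numpy(), n_bins, 180.0)
    err = out["error"].to_numpy()
    bias = np.zeros(n_bins)
    for b in range(n_bins):
        sel = tb == b
        if sel.sum() < 2:
            continue
        s = circ_mean_var(err[sel] % 180.0, period=180.0)
        if s.mean_defined:
            bias[b] = circ_error(s.mean, 0.0, period=180.0)
    out["error_bc"] = circ_error(err, bias[tb], period=180.0)
    return out


def trial_corr(
    trials_a: pd.DataFrame,
    trials_b: pd.DataFrame,
    corrected: bool = False,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Circular correlation of trial-by-trial (optionally bias-corrected) errors.

    The two trial tables must cover the same stimulus ids; rows are aligned
    by id. Returns the Fisher-Lee coefficient and a percentile bootstrap CI.
    """
    a = trials_a.sort_values("stimulus_id").reset_index(drop=True)
    b = trials_b.sort_values("stimulus_id").reset_index(drop=True)
    if len(a) != len(b) or not np.array_equal(a["stimulus_id"].to_numpy(), b["stimulus_id"].to_numpy()):
        raise ValueError("trial sets must share the same stimulus ids")
    col = "error_bc" if corrected else "error"
    if corrected and ("error_bc" not in a or "error_bc" not in b):
        a, b = bias_correct(a), bias_correct(b)
    ea, eb = a[col].to_numpy(), b[col].to_numpy()
    r = circ_corr(ea, eb, period=180.0)
    ci = bootstrap_ci(
        lambda x, y: circ_corr(x, y, period=180.0), (ea, eb), n_boot=n_boot, level=level, seed=seed
    )
    return r, ci


def variance_explained(reference, model, angular: bool = False, period: float = 180.0) -> float:
    """Proportion of variance explained, R^2 = 1 - SSres/SStot.

    For angular statistics, residuals and total deviations use circular
    distance (the reference's circular mean as the null model); for counts
    and variances, ordinary differences. May be negative; NaN when the
    reference has zero total variance.
    """
    ref = np.asarray(reference, dtype=float)
    mod = np.asarray(model, dtype=float)
    if ref.shape != mod.shape:
        raise ValueError("stat vectors must have equal length")
    if angular:
        res = circ_error(mod, ref, period=period)
        center = circ_mean_var(ref, period=period).mean
        tot = circ_error(ref, center, period=period)
    else:
        res = mod - ref
        tot = ref - ref.mean()
    ss_tot = float(np.sum(np.square(tot)))
    if ss_tot <= 0:
        return float("nan")
    return float(1.0 - np.sum(np.square(res)) / ss_tot)


def covariate_effect(
    trials: pd.DataFrame,
    covariate: str,
    binning: str = "quantile",
    n_bins: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Mean absolute error per covariate bin plus a least-squares slope.

    ``binning='quantile'`` groups trials into equal-count bins (ties broken
    by stable order); ``'fixed'`` uses equal-width bins. Returns
    ``(table, slope)`` where the table has bin centers, mean |error| and
    counts, and the slope is from an ordinary least-squares line through the
    bin means.
    """
    if covariate not in ("slant", "distance", "tilt_variance"):
        raise ValueError(f"unsupported covariate: {covariate!r}")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    x = trials[covariate].to_numpy(dtype=float)
    abs_err = np.abs(trials["error"].to_numpy(dtype=float))
    if binning == "quantile":
        order = np.argsort(x, kind="stable")
        idx = np.empty(x.size, dtype=int)
        idx[order] = np.minimum((np.arange(x.size) * n_bins) // x.size, n_bins - 1)
    elif binning == "fixed":
        lo, hi = x.min(), x.max()
        width = (hi - lo) / n_bins or 1.0
        idx = np.clip(((x - lo) / width).astype(int), 0, n_bins - 1)
    else:
        raise ValueError(f"unknown binning: {binning!r}")
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append(
            {"bin": b, "center": float(x[sel].mean()), "mean_abs_error": float(abs_err[sel].mean()), "count": int(sel.sum())}
        )
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        slope = float(np.polyfit(table["center"], table["mean_abs_error"], 1)[0])
    else:
        slope = float("nan")
    return table, slope


def cardinal_oblique_split(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition trials by truth tilt into cardinal and oblique subsets.

    Cardinal: within 22.5 deg (exclusive) of 0 or 90; oblique: the rest
    (the 45 +/- 22.5 and 135 +/- 22.5 windows, boundary included). Disjoint
    and exhaustive.
    """
    tau = trials["truth_tilt"].to_numpy(dtype=float) % 180.0
    d0 = np.abs(circ_error(tau, 0.0, period=180.0))
    d90 = np.abs(circ_error(tau, 90.0, period=180.0))
    is_cardinal = (d0 < 22.5) | (d90 < 22.5)
    return trials[is_cardinal], trials[~is_cardinal]


def monte_carlo_experiment(
    simulate_fn: Callable[[int], dict[str, np.ndarray]],
    n_repeats: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Percentile confidence bands over repeated simulated experiments.

    ``simulate_fn(repeat_seed)`` runs one experiment repeat (a fresh
    stimulus sample) and returns a dict of named statistic vectors; this
    function calls it ``n_repeats`` times with seeds derived from ``seed``
    and returns per-statistic (lo, hi) percentile bands. Failed repeats are
    skipped and counted in ``monte_carlo_experiment.last_n_failed``.
    """
    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    collected: dict[str, list[np.ndarray]] = {}
    failed = 0
    for s in repeat_seeds:
        try:
            stats = simulate_fn(int(s))
        except Exception:
            failed += 1
            continue
        for name, vec in stats.items():
            collected.setdefault(name, []).append(np.asarray(vec, dtype=float))
    monte_carlo_experiment.last_n_failed = failed
    if not collected:
        raise RuntimeError("all Monte Carlo repeats failed")
    alpha = (1.0 - level) / 2.0
    bands = {}
    for name, vecs in collected.items():
        stack = np.stack(vecs)
        bands[name] = (
            np.nanquantile(stack, alpha, axis=0),
            np.nanquantile(stack, 1.0 - alpha, axis=0),
        )
    return bands


monte_carlo_experiment.last_n_failed = 0
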