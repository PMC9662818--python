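"""Sliding-window firing-rate dynamics.

The 30-min linear-chamber epoch is tiled with 3-s windows advanced in 1-s
steps, giving exactly 1800 instantaneous firing rates per unit (windows at
the epoch end are truncated).  From that series come the firing-rate range
(max - min), sigma (one sample SD — the study's firing-variability measure),
normalized-rate histograms, per-session statistics, a log-log sigma-vs-mean
regression with a between-group slope/elevation comparison, and the maximum
delta firing rate between the two in-zones and the center zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import IntervalSet, count_spikes_in_intervals


@dataclass
class DynamicsSummary:
    mean_rate: float
    max_rate: float
    min_rate: float
    fr_range: float
    sigma: float
    per_session: dict[str, "DynamicsSummary"]


@dataclass
class MaxDeltaFR:
    fr_c: float
    fr_i1: float
    fr_i2: float
    max_delta: float
    normalized_max_delta: float


def instantaneous_rates(spikes: np.ndarray, epoch: tuple[float, float],
                        window_s: float = 3.0,
                        step_s: float = 1.0) -> np.ndarray:
    """Rates in sliding windows anchored every ``step_s`` over the epoch.

    Window k covers [t0 + k*step, min(t0 + k*step + window, t1)); the count
    of windows is exactly (t1 - t0) / step, with end windows truncated and
    their rates computed over the actual window length.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    t0, t1 = epoch
    n_windows = int(round((t1 - t0) / step_s))
    if abs(n_windows * step_s - (t1 - t0)) > 1e-9:
        raise ValueError("epoch duration must be a multiple of step_s")
    spikes = np.asarray(spikes, dtype=float)
    starts = t0 + step_s * np.arange(n_windows)
    ends = np.minimum(starts + window_s, t1)
    counts = np.searchsorted(spikes, ends) - np.searchsorted(spikes, starts)
    return counts / (ends - starts)


def _stats(values: np.ndarray, per_session: dict | None = None) -> DynamicsSummary:
    return DynamicsSummary(
        mean_rate=float(values.mean()),
        max_rate=float(values.max()),
        min_rate=float(values.min()),
        fr_range=float(values.max() - values.min()),
        sigma=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        per_session=per_session or {})


def summarize_dynamics(values: np.ndarray, epoch: tuple[float, float],
                       session_bounds: dict[str, tuple[float, float]] | None = None,
                       step_s: float = 1.0) -> DynamicsSummary:
    """Range, sigma (sample SD), and mean of an instantaneous-rate series,
    optionally split per session.  A window belongs to the session containing
    its start."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty rate series")
    per_session: dict[str, DynamicsSummary] = {}
    if session_bounds:
        starts = epoch[0] + step_s * np.arange(len(values))
        for name, (s0, s1) in session_bounds.items():
            sel = (starts >= s0) & (starts < s1)
            if sel.any():
                per_session[name] = _stats(values[sel])
    return _stats(values, per_session)


def normalized_rate_histogram(values: np.ndarray,
                              bin_width: float = 0.1) -> np.ndarray:
    """Histogram of rates normalized by the series maximum, as proportions
    over [0, 1] in 0.1-wide bins (the top bin is right-closed)."""
    values = np.asarray(values, dtype=float)
    peak = values.max() if len(values) else 0.0
    if peak <= 0:
        raise ValueError("normalized histogram undefined for an all-zero series")
    n_bins = int(round(1.0 / bin_width))
    counts, _ = np.histogram(values / peak, bins=n_bins, range=(0.0, 1.0))
    return counts / len(values)


@dataclass
class SigmaMeanFit:
    slope: float
    intercept: float
    n: int


def fit_log_sigma_vs_mean(means: np.ndarray,
                          sigmas: np.ndarray) -> SigmaMeanFit:
    """OLS of log10(sigma) on log10(mean rate); nonpositive units dropped."""
    means = np.asarray(means, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    good = (means > 0) & (sigmas > 0)
    if not good.all():
        warnings.warn(f"dropping {int((~good).sum())} unit(s) with "
                      "nonpositive mean or sigma from the log-log fit")
    x, y = np.log10(means[good]), np.log10(sigmas[good])
    if len(x) < 3:
        raise ValueError("need at least 3 units with positive mean and sigma")
    slope, intercept = np.polyfit(x, y, 1)
    return SigmaMeanFit(float(slope), float(intercept), len(x))


def sigma_vs_mean_regression(groups: dict[str, tuple[np.ndarray, np.ndarray]]):
    """Per-group log-log fits plus the two-group slope/elevation comparison.

    ``groups`` maps group name -> (mean rates, sigmas).  Returns
    (fits, comparison); the comparison is done for exactly two groups (the
    genotype contrast) and is None otherwise.
    """
    from .pipeline import compare_slopes  # local import avoids a cycle

    fits = {name: fit_log_sigma_vs_mean(m, s) for name, (m, s) in groups.items()}
    comparison = None
    if len(groups) == 2:
        (m1, s1), (m2, s2) = groups.values()
        def logpts(m, s):
            m = np.asarray(m, float); s = np.asarray(s, float)
            good = (m > 0) & (s > 0)
            return np.log10(m[good]), np.log10(s[good])
        x1, y1 = logpts(m1, s1)
        x2, y2 = logpts(m2, s2)
        comparison = compare_slopes(x1, y1, x2, y2)
    return fits, comparison


def max_delta_fr(spikes: np.ndarray, inzone_iv_1: IntervalSet,
                 inzone_iv_2: IntervalSet,
                 center_iv: IntervalSet) -> MaxDeltaFR:
    """Largest absolute in-zone-vs-center rate difference for one session,
    and its normalized form max |(FR_I - FR_C) / (FR_I + FR_C)|."""
    def zone_rate(iv: IntervalSet) -> float:
        dur = iv.total_duration
        if dur <= 0:
            raise ValueError(f"zone {iv.label!r} has zero total duration")
        return count_spikes_in_intervals(spikes, iv) / dur

    fr_i1, fr_i2, fr_c = (zone_rate(iv) for iv in
                          (inzone_iv_1, inzone_iv_2, center_iv))
    max_delta = max(abs(fr_i1 - fr_c), abs(fr_i2 - fr_c))

    def norm(fr_i: float) -> float:
        denom = fr_i + fr_c
        return 0.0 if denom == 0 else abs((fr_i - fr_c) / denom)

    return MaxDeltaFR(fr_c, fr_i1, fr_i2, max_delta,
                      max(norm(fr_i1), norm(fr_i2)))
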