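"""Target-responsive neuron calling and response characterization.

A unit is called empty/social/object-responsive when the area under the ROC
curve (auROC) comparing its instantaneous firing-rate distribution during
target sniffing against that in the center zone falls outside the 0.5% /
99.5% quantiles of a label-shuffled null (1000 shuffles).  Instantaneous
rates are spike counts in consecutive 0.5-s bins; the ROC is built by
sweeping a threshold across the pooled rate range in 100 steps.  auROC > 0.5
marks an increasing response, < 0.5 a decreasing one.  The module also
provides peri-sniff spike density functions, center-referenced z-scores, and
trial-to-trial consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IntervalSet, count_spikes_in_intervals


@dataclass
class CenterStats:
    """Mean and SD of center-zone instantaneous rates (0.5-s bins)."""

    mu_c: float
    sigma_c: float
    n_bins: int


@dataclass
class TargetNeuronResult:
    unit_id: str
    target: str
    auroc: float | None
    null_quantiles: tuple[float, float] | None
    label: str  # responsive / nonresponsive / insufficient_data
    direction: str  # increasing / decreasing / n/a


def binned_rates(spikes: np.ndarray, iv: IntervalSet,
                 bin_s: float = 0.5) -> np.ndarray:
    """Instantaneous rates: each interval is cut into consecutive ``bin_s``
    bins from its start; a trailing remainder shorter than ``bin_s`` is
    discarded.  Rate = count / bin_s."""
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    spikes = np.asarray(spikes, dtype=float)
    rates: list[np.ndarray] = []
    for start, end in iv.intervals:
        n_bins = int(np.floor((end - start) / bin_s + 1e-9))
        if n_bins == 0:
            continue
        edges = start + bin_s * np.arange(n_bins + 1)
        counts = np.diff(np.searchsorted(spikes, edges))
        rates.append(counts / bin_s)
    if not rates:
        return np.empty(0)
    return np.concatenate(rates)


def _sweep_thresholds(pooled: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(pooled.min()), float(pooled.max())
    return np.linspace(lo, hi, n_bins + 1)


def _roc_area(tpr: np.ndarray, fpr: np.ndarray) -> np.ndarray:
    """Area under curves given per-threshold (tpr, fpr), thresholds ascending.

    As the threshold rises both probabilities fall from P(x > min) to 0; the
    curve is closed at (0, 0) and (1, 1) and integrated by trapezoids.
    """
    tpr = np.atleast_2d(tpr)
    fpr = np.atleast_2d(fpr)
    n = tpr.shape[0]
    ones = np.ones((n, 1))
    zeros = np.zeros((n, 1))
    # threshold ascending => x descending; flip to integrate left-to-right
    x = np.hstack([ones, fpr, zeros])[:, ::-1]
    y = np.hstack([ones, tpr, zeros])[:, ::-1]
    return np.trapezoid(y, x, axis=1)


def auroc(sniff: np.ndarray, center: np.ndarray,
          n_threshold_bins: int = 100) -> float:
    """ROC-sweep area: P(sniff rate > thr) against P(center rate > thr) for
    a threshold swept over the pooled [min, max] range in 100 steps."""
    sniff = np.asarray(sniff, dtype=float)
    center = np.asarray(center, dtype=float)
    if len(sniff) == 0 or len(center) == 0:
        raise ValueError("auroc needs non-empty rate samples")
    thr = _sweep_thresholds(np.concatenate([sniff, center]), n_threshold_bins)
    tpr = (sniff[:, None] > thr[None, :]).mean(axis=0)
    fpr = (center[:, None] > thr[None, :]).mean(axis=0)
    return float(_roc_area(tpr, fpr)[0])


def shuffled_aurocs(sniff: np.ndarray, center: np.ndarray, n_shuffles: int,
                    rng: np.random.Generator,
                    n_threshold_bins: int = 100) -> np.ndarray:
    """auROCs after random re-partition of the pooled rates into groups of
    the original sizes (label permutation), vectorized over shuffles."""
    pooled = np.concatenate([sniff, center])
    n, n_s = len(pooled), len(sniff)
    thr = _sweep_thresholds(pooled, n_threshold_bins)
    above = (pooled[:, None] > thr[None, :]).astype(float)  # (n, thr)
    perms = np.argsort(rng.random((n_shuffles, n)), axis=1)
    sel = np.zeros((n_shuffles, n))
    rows = np.repeat(np.arange(n_shuffles), n_s)
    sel[rows, perms[:, :n_s].ravel()] = 1.0
    tpr = sel @ above / n_s
    fpr = (1.0 - sel) @ above / (n - n_s)
    return _roc_area(tpr, fpr)


def classify_target_neuron(spikes: np.ndarray, sniff_iv: IntervalSet,
                           center_iv: IntervalSet, n_shuffles: int = 1000,
                           min_bins: int = 40, bin_s: float = 0.5,
                           seed: int | np.random.Generator | None = None,
                           unit_id: str = "", target: str = "",
                           quantiles: tuple[float, float] = (0.005, 0.995),
                           ) -> TargetNeuronResult:
    """Permutation test of the observed auROC against its shuffled null.

    Responsive iff the observed auROC is strictly above the 99.5% or
    strictly below the 0.5% quantile of 1000 shuffled auROCs.  Units with
    fewer than 40 rate bins (20 s) in either context are not classified.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sniff = binned_rates(spikes, sniff_iv, bin_s)
    center = binned_rates(spikes, center_iv, bin_s)
    if len(sniff) < min_bins or len(center) < min_bins:
        return TargetNeuronResult(unit_id, target, None, None,
                                  "insufficient_data", "n/a")
    res = permutation_call(sniff, center, n_shuffles, rng, quantiles)
    res.unit_id, res.target = unit_id, target
    return res


def permutation_call(sniff: np.ndarray, center: np.ndarray, n_shuffles: int,
                     rng: np.random.Generator,
                     quantiles: tuple[float, float] = (0.005, 0.995),
                     ) -> TargetNeuronResult:
    """Apply the auROC-vs-shuffled-null decision rule to rate samples."""
    observed = auroc(sniff, center)
    null = shuffled_aurocs(sniff, center, n_shuffles, rng)
    q_lo, q_hi = np.quantile(null, quantiles)
    responsive = observed > q_hi or observed < q_lo
    direction = "n/a"
    if responsive:
        direction = "increasing" if observed > 0.5 else "decreasing"
    return TargetNeuronResult("", "", observed, (float(q_lo), float(q_hi)),
                              "responsive" if responsive else "nonresponsive",
                              direction)


# ---------------------------------------------------------------------------
# Spike density functions
# ---------------------------------------------------------------------------

def spike_density_function(spikes: np.ndarray, sniff_onsets: np.ndarray,
                           window: tuple[float, float] = (-1.5, 3.0),
                           bin_s: float = 0.25) -> np.ndarray:
    """Trial-averaged binned rates aligned to sniff onset (18 bins of 250 ms
    from -1.5 s to +3 s by default)."""
    onsets = np.asarray(sniff_onsets, dtype=float)
    if len(onsets) == 0:
        raise ValueError("spike_density_function needs at least one onset")
    spikes = np.asarray(spikes, dtype=float)
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    per_trial = np.empty((len(onsets), len(edges) - 1))
    for i, t in enumerate(onsets):
        counts = np.diff(np.searchsorted(spikes, t + edges))
        per_trial[i] = counts / bin_s
    return per_trial.mean(axis=0)


def normalize_sdfs(sdfs: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Normalize a unit's per-target SDFs by their joint maximum, so the
    largest response across the unit's targets reads 1."""
    peak = max(float(np.max(v)) for v in sdfs.values())
    if peak <= 0:
        return {k: np.zeros_like(v) for k, v in sdfs.items()}
    return {k: v / peak for k, v in sdfs.items()}


# ---------------------------------------------------------------------------
# z-scores and consistency
# ---------------------------------------------------------------------------

def compute_center_stats(spikes: np.ndarray, center_iv: IntervalSet,
                         bin_s: float = 0.5) -> CenterStats:
    rates = binned_rates(spikes, center_iv, bin_s)
    if len(rates) == 0:
        raise ValueError("no center-zone rate bins")
    return CenterStats(float(rates.mean()), float(rates.std(ddof=1)),
                       len(rates))


def target_zscore(spikes: np.ndarray, target_iv: IntervalSet,
                  center_stats: CenterStats) -> float:
    """(FR_T - mu_C) / sigma_C with FR_T the mean rate during sniffing."""
    if center_stats.sigma_c <= 0:
        raise ValueError("degenerate center-zone statistics (sigma = 0)")
    dur = target_iv.total_duration
    if dur <= 0:
        raise ValueError("target intervals have zero duration")
    fr_t = count_spikes_in_intervals(spikes, target_iv) / dur
    return (fr_t - center_stats.mu_c) / center_stats.sigma_c


def per_trial_zscores(spikes: np.ndarray, target_iv: IntervalSet,
                      center_stats: CenterStats) -> np.ndarray:
    """One z-score per sniffing trial, from interaction onset to end."""
    if center_stats.sigma_c <= 0:
        raise ValueError("degenerate center-zone statistics (sigma = 0)")
    spikes = np.asarray(spikes, dtype=float)
    z = np.empty(len(target_iv))
    for i, (start, end) in enumerate(target_iv.intervals):
        lo, hi = np.searchsorted(spikes, [start, end])
        fr = (hi - lo) / (end - start)
        z[i] = (fr - center_stats.mu_c) / center_stats.sigma_c
    return z


def trial_consistency(per_trial_z: np.ndarray, direction: str) -> float:
    """Percent of trials whose z-score matches the unit's response direction
    (z > 0 for increasing, z < 0 for decreasing; z = 0 counts against)."""
    z = np.asarray(per_trial_z, dtype=float)
    if len(z) == 0:
        raise ValueError("trial_consistency needs at least one trial")
    if direction == "increasing":
        return 100.0 * float((z > 0).mean())
    if direction == "decreasing":
        return 100.0 * float((z < 0).mean())
    raise ValueError(f"unknown direction {direction!r}")
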