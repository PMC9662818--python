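"""Interspike-interval and burst-firing analyses.

Burst spikes are consecutive spikes joined by interspike intervals at or
below a threshold (default 10 ms; chains count every member).  The module
computes ISI histograms (ISIs <= 200 ms, 1-ms bins), burst proportions over
a range of thresholds (5-30 ms), per-epoch burst statistics (ISIs are never
taken across an epoch boundary), and the burst/tonic spike-elimination
transforms used to re-run downstream analyses on partial trains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import restrict_spikes


@dataclass
class ISIHistogram:
    bin_width_ms: float
    max_isi_ms: float
    edges_ms: np.ndarray
    counts: np.ndarray
    proportions: np.ndarray  # counts / all ISIs (including those > max)
    n_isis_total: int


@dataclass
class BurstStats:
    threshold_ms: float
    n_burst_spikes: int
    n_total_spikes: int

    @property
    def burst_proportion(self) -> float:
        """Percent of spikes participating in a burst; NaN for empty trains."""
        if self.n_total_spikes == 0:
            return float("nan")
        return 100.0 * self.n_burst_spikes / self.n_total_spikes


def isi_histogram(spikes: np.ndarray, bin_width_ms: float = 1.0,
                  max_isi_ms: float = 200.0) -> ISIHistogram:
    """Histogram of ISIs <= max_isi_ms; proportions are normalized by the
    total ISI count so they sum to the fraction of ISIs within range."""
    spikes = np.asarray(spikes, dtype=float)
    edges = np.arange(0.0, max_isi_ms + bin_width_ms / 2, bin_width_ms)
    if len(spikes) < 2:
        z = np.zeros(len(edges) - 1)
        return ISIHistogram(bin_width_ms, max_isi_ms, edges, z, z.copy(), 0)
    isis_ms = np.diff(spikes) * 1000.0
    counts, _ = np.histogram(isis_ms[isis_ms <= max_isi_ms], bins=edges)
    return ISIHistogram(bin_width_ms, max_isi_ms, edges,
                        counts.astype(float), counts / len(isis_ms),
                        len(isis_ms))


def mean_isi_histogram(histograms: Iterable[ISIHistogram]) -> np.ndarray:
    """Group-average of per-unit normalized ISI histograms."""
    props = [h.proportions for h in histograms]
    if not props:
        raise ValueError("no histograms to average")
    return np.mean(props, axis=0)


def _burst_mask(spikes: np.ndarray, threshold_ms: float) -> np.ndarray:
    """True for spikes participating in at least one ISI <= threshold."""
    if len(spikes) < 2:
        return np.zeros(len(spikes), dtype=bool)
    short = np.diff(spikes) <= threshold_ms / 1000.0
    mask = np.zeros(len(spikes), dtype=bool)
    mask[:-1] |= short
    mask[1:] |= short
    return mask


def burst_proportion(spikes: np.ndarray,
                     threshold_ms: float = 10.0) -> BurstStats:
    spikes = np.asarray(spikes, dtype=float)
    if len(spikes) == 0:
        raise ValueError("burst_proportion needs at least one spike")
    mask = _burst_mask(spikes, threshold_ms)
    return BurstStats(threshold_ms, int(mask.sum()), len(spikes))


def eliminate_spikes(spikes: np.ndarray, mode: str,
                     threshold_ms: float = 10.0) -> np.ndarray:
    """Remove burst-participating spikes (mode='burst') or everything else
    (mode='tonic'); the two outputs partition the input train."""
    spikes = np.asarray(spikes, dtype=float)
    mask = _burst_mask(spikes, threshold_ms)
    if mode == "burst":
        return spikes[~mask]
    if mode == "tonic":
        return spikes[mask]
    raise ValueError(f"unknown elimination mode {mode!r}")


def burst_rest_vs_chamber(spikes: np.ndarray,
                          rest_epoch: tuple[float, float],
                          chamber_epoch: tuple[float, float],
                          thresholds_ms: Iterable[float] = tuple(range(5, 31)),
                          ) -> dict[str, dict[float, BurstStats]]:
    """Burst proportion per epoch per threshold; spikes are restricted to
    the epoch before ISIs are formed, so no ISI crosses the boundary.
    Epochs without spikes yield stats with a NaN proportion."""
    out: dict[str, dict[float, BurstStats]] = {}
    for name, (t0, t1) in (("rest", rest_epoch), ("chamber", chamber_epoch)):
        sub = restrict_spikes(spikes, t0, t1)
        out[name] = {}
        for thr in thresholds_ms:
            if len(sub) == 0:
                out[name][thr] = BurstStats(thr, 0, 0)
            else:
                out[name][thr] = burst_proportion(sub, thr)
    return out
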