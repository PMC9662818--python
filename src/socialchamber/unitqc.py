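"""Unit classification and inclusion filters.

Units are split into putative excitatory (pExc) and putative inhibitory
(pInh) classes from two waveform features — half-valley width and
peak-to-valley ratio — with strict thresholds (pExc: both above 200 / 1.4,
pInh: both below).  Discordant feature pairs are left unclassified and
excluded downstream.  Inclusion further requires cluster quality (isolation
distance > 25, L-ratio < 0.1), a mean firing rate of at least 0.5 Hz over
the 30-min linear-chamber epoch, and at least one valid sniffing and one
valid in-zone trial for each of the six per-session targets.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .core import (SIX_TARGETS, IntervalSet, UnitRecord, WaveformFeatures,
                   restrict_spikes)


def classify_unit(f: WaveformFeatures, hvw_threshold: float = 200.0,
                  pvr_threshold: float = 1.4) -> str:
    """'pExc', 'pInh', or 'unclassified' (discordant or exactly on-threshold)."""
    if f.hvw > hvw_threshold and f.pvr > pvr_threshold:
        return "pExc"
    if f.hvw < hvw_threshold and f.pvr < pvr_threshold:
        return "pInh"
    return "unclassified"


def quality_filter(u: UnitRecord, min_isolation_distance: float = 25.0,
                   max_l_ratio: float = 0.1) -> bool:
    if u.isolation_distance is None or u.l_ratio is None:
        raise ValueError(f"unit {u.unit_id}: missing cluster-quality metadata")
    return u.isolation_distance > min_isolation_distance and u.l_ratio < max_l_ratio


def rate_filter(u: UnitRecord, chamber_epoch: tuple[float, float],
                min_rate_hz: float = 0.5) -> bool:
    """Mean rate over the linear-chamber epoch at or above 0.5 Hz (inclusive).

    Rest-period firing-rate comparisons bypass this filter by design.
    """
    t0, t1 = chamber_epoch
    if t1 <= t0:
        raise ValueError("chamber epoch must have positive duration")
    n = len(restrict_spikes(u.spikes, t0, t1))
    return n / (t1 - t0) >= min_rate_hz


def exclude_units_missing_trials(
        units: Sequence[UnitRecord],
        valid_sniff: Mapping[tuple[str, str], IntervalSet],
        valid_inzone: Mapping[tuple[str, str], IntervalSet]) -> list[UnitRecord]:
    """All units of an experiment are dropped if any of the six targets has
    no valid sniffing or no valid in-zone trial."""
    for key in SIX_TARGETS:
        if len(valid_sniff.get(key, IntervalSet("x", "x", []))) == 0:
            return []
        if len(valid_inzone.get(key, IntervalSet("x", "x", []))) == 0:
            return []
    return list(units)


def qc_report(units: Sequence[UnitRecord],
              chamber_epoch: tuple[float, float],
              valid_sniff: Mapping[tuple[str, str], IntervalSet],
              valid_inzone: Mapping[tuple[str, str], IntervalSet],
              min_rate_hz: float = 0.5) -> pd.DataFrame:
    """Per-unit QC table and the combined inclusion decision."""
    trials_ok = len(exclude_units_missing_trials(units, valid_sniff,
                                                 valid_inzone)) > 0
    rows = []
    for u in units:
        cls = classify_unit(u.features)
        pass_quality = quality_filter(u)
        pass_rate = rate_filter(u, chamber_epoch, min_rate_hz)
        included = (cls == "pExc" and pass_quality and pass_rate and trials_ok)
        u.cell_class = cls
        u.included = included
        if not included:
            u.exclusion_reason = (
                "not pExc" if cls != "pExc" else
                "cluster quality" if not pass_quality else
                "rate below threshold" if not pass_rate else
                "missing valid trials")
        rows.append({"unit_id": u.unit_id, "cell_class": cls,
                     "pass_quality": pass_quality, "pass_rate": pass_rate,
                     "pass_trials": trials_ok, "included": included})
    return pd.DataFrame(rows)
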