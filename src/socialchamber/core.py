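"""Shared domain types for linear-chamber social-interaction spike analysis.

The experiment timeline is a single absolute clock in seconds: a rest epoch
(default 5 min) followed by three 10-min linear-chamber sessions (empty-empty
"EE", first social-object "fSO", second social-object "sSO").  All intervals
are half-open ``[start, end)`` and 0-based on that clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

SESSION_NAMES = ("EE", "fSO", "sSO")

#: Targets a unit can be classified against (sniff bins pooled as in the
#: analysis: empty over the EE session, social/object over both S-O sessions).
CLASS_TARGETS = ("empty", "social", "object")

#: The six per-session targets used for valid-trial bookkeeping.
SIX_TARGETS = (
    ("EE", "left"),
    ("EE", "right"),
    ("fSO", "social"),
    ("fSO", "object"),
    ("sSO", "social"),
    ("sSO", "object"),
)

SUBJECT_PARTS = ("nose", "left_ear", "right_ear", "body_center", "tail_base")
TARGET_PARTS = ("target_nose", "target_body_center")


@dataclass(frozen=True)
class SessionLayout:
    """Timing and geometry of the rest box + linear-chamber paradigm."""

    rest_duration: float = 300.0
    session_durations: tuple[float, float, float] = (600.0, 600.0, 600.0)
    fps: float = 30.0
    chamber_length: float = 45.0
    chamber_width: float = 10.0

    def __post_init__(self) -> None:
        if self.rest_duration <= 0 or any(d <= 0 for d in self.session_durations):
            raise ValueError("all durations must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @property
    def total_duration(self) -> float:
        return self.rest_duration + float(sum(self.session_durations))

    @property
    def chamber_epoch(self) -> tuple[float, float]:
        """The 30-min linear-chamber window (excludes the rest epoch)."""
        return (self.rest_duration, self.total_duration)

    def session_bounds(self) -> dict[str, tuple[float, float]]:
        bounds = {}
        t0 = self.rest_duration
        for name, dur in zip(SESSION_NAMES, self.session_durations):
            bounds[name] = (t0, t0 + dur)
            t0 += dur
        return bounds


@dataclass(frozen=True)
class ZoneGeometry:
    """Zone definitions along the 45-cm corridor (cm).

    The sniffing zone is the 3-cm band at each chamber face, the in-zone the
    9-cm band, and the center zone the middle of the five equal 9-cm sections.
    Proximal / distal interactions split nose-to-target distance at 2.5 cm
    and 10 cm.
    """

    sniff_depth: float = 3.0
    inzone_depth: float = 9.0
    section_length: float = 9.0
    proximal_max: float = 2.5
    distal_max: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.sniff_depth < self.inzone_depth <= self.section_length):
            raise ValueError("need 0 < sniff_depth < inzone_depth <= section_length")
        if not self.proximal_max < self.distal_max:
            raise ValueError("proximal_max must be < distal_max")


@dataclass
class TrackingSeries:
    """Per-frame body-part coordinates for one session, in chamber cm.

    ``parts`` maps part name -> (n_frames, 3) array of (x, y, likelihood).
    ``timestamps`` are absolute experiment seconds, uniform at 1/fps.
    """

    session: str
    timestamps: np.ndarray
    parts: dict[str, np.ndarray]

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def frame_dt(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    def require(self, *names: str) -> None:
        for name in names:
            if name not in self.parts:
                raise KeyError(f"tracking series is missing body part {name!r}")

    def xy(self, part: str) -> np.ndarray:
        self.require(part)
        return self.parts[part][:, :2]

    def likelihood(self, part: str) -> np.ndarray:
        self.require(part)
        return self.parts[part][:, 2]


@dataclass
class IntervalSet:
    """Labeled, sorted, non-overlapping half-open time intervals (seconds)."""

    label: str
    session: str
    intervals: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if len(iv):
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError("intervals must satisfy end > start")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("intervals must be sorted and non-overlapping")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum()) if len(self) else 0.0


def merge_interval_sets(sets: Sequence[IntervalSet], label: str,
                        session: str = "pooled") -> IntervalSet:
    """Concatenate interval sets in time order (inputs must not overlap)."""
    if not sets:
        return IntervalSet(label, session, np.empty((0, 2)))
    iv = np.concatenate([s.intervals for s in sets]) if any(len(s) for s in sets) \
        else np.empty((0, 2))
    order = np.argsort(iv[:, 0]) if len(iv) else slice(None)
    return IntervalSet(label, session, iv[order])


def restrict_spikes(spikes: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Spikes within the half-open epoch [t0, t1)."""
    spikes = np.asarray(spikes, dtype=float)
    lo, hi = np.searchsorted(spikes, [t0, t1])
    return spikes[lo:hi]


def count_spikes_in_intervals(spikes: np.ndarray, iv: IntervalSet) -> int:
    spikes = np.asarray(spikes, dtype=float)
    if not len(iv):
        return 0
    lo = np.searchsorted(spikes, iv.intervals[:, 0])
    hi = np.searchsorted(spikes, iv.intervals[:, 1])
    return int((hi - lo).sum())


@dataclass(frozen=True)
class WaveformFeatures:
    """Scalar waveform features used for putative cell-type classification."""

    hvw: float  # half-valley width, stored units match the 200 threshold
    pvr: float  # peak-to-valley ratio

    def __post_init__(self) -> None:
        if self.hvw <= 0 or self.pvr <= 0:
            raise ValueError("waveform features must be > 0")


@dataclass
class UnitRecord:
    """One recorded unit: spike train plus QC metadata and classifications."""

    unit_id: str
    spikes: np.ndarray
    features: WaveformFeatures
    isolation_distance: float
    l_ratio: float
    cell_class: str | None = None  # pExc / pInh / unclassified
    included: bool | None = None
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=float)
        if np.any(np.diff(self.spikes) < 0):
            raise ValueError(f"unit {self.unit_id}: spike train not sorted")


@dataclass
class UnitSpec:
    """Ground-truth generator parameters for one synthetic unit."""

    genotype: str  # WT / KO
    baseline_rate: float
    rest_rate: float
    target_gains: dict[str, float]
    burst_propensity: float
    hvw: float
    pvr: float
    isolation_distance: float
    l_ratio: float
    is_social_neuron: bool
    intra_burst_isi: float = 0.005

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.rest_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.burst_propensity <= 1.0:
            raise ValueError("burst_propensity must be in [0, 1]")
        if self.hvw <= 0 or self.pvr <= 0:
            raise ValueError("hvw and pvr must be > 0")


@dataclass
class ExperimentBundle:
    """A complete (synthetic) experiment: layout, tracking, units, truth."""

    layout: SessionLayout
    tracking: dict[str, TrackingSeries]
    units: list[UnitRecord]
    truth: dict[str, UnitSpec]
    seed: int
    social_side: dict[str, str] = field(
        default_factory=lambda: {"fSO": "left", "sSO": "right"})

    def target_side(self, session: str, target: str) -> str:
        """Which face ('left'/'right') a named target occupies in a session."""
        if session == "EE":
            return target
        social = self.social_side[session]
        if target == "social":
            return social
        return "right" if social == "left" else "left"


# Analysis parameter defaults, as printed in the study they reproduce.  The
# functions carry the same defaults; this registry exists so a single audit
# can assert the two never drift apart.
DEFAULTS: Mapping[str, float | int | tuple] = {
    "sniff_depth_cm": 3.0,
    "inzone_depth_cm": 9.0,
    "section_length_cm": 9.0,
    "proximal_max_cm": 2.5,
    "distal_max_cm": 10.0,
    "sniff_min_duration_s": 1.0,
    "sniff_min_gap_s": 2.0,
    "inzone_min_duration_s": 0.5,
    "inzone_min_gap_s": 0.5,
    "proximity_min_duration_s": 1.0,
    "rate_bin_s": 0.5,
    "roc_threshold_bins": 100,
    "n_shuffles": 1000,
    "null_quantiles": (0.005, 0.995),
    "min_rate_bins": 40,
    "sdf_bin_s": 0.25,
    "sdf_window_s": (-1.5, 3.0),
    "min_trials_per_class": 10,
    "decoding_repetitions": 100,
    "correct_neuron_threshold_pct": 55.0,
    "rate_window_s": 3.0,
    "rate_step_s": 1.0,
    "n_rate_windows": 1800,
    "isi_max_ms": 200.0,
    "isi_bin_ms": 1.0,
    "burst_threshold_ms": 10.0,
    "burst_threshold_sweep_ms": (5.0, 30.0),
    "min_chamber_rate_hz": 0.5,
    "hvw_threshold": 200.0,
    "pvr_threshold": 1.4,
    "min_isolation_distance": 25.0,
    "max_l_ratio": 0.1,
    "current_step_s": 0.5,
    "current_range_pa": (-300.0, 400.0),
    "current_increment_pa": 50.0,
    "dvdt_threshold_mv_per_ms": 5.0,
}
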