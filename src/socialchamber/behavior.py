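"""Behavioral event extraction from pose tracks.

Converts per-frame body-part coordinates into labeled interval sets:
sniffing (nose within 3 cm of a chamber face), in-zone (body center within
9 cm), center zone (middle 9-cm section of the corridor), and proximal /
distal interactions (nose-to-target distance below 2.5 cm / between 2.5 and
10 cm).  The body center used for zone membership is the geometric midpoint
of the tracked nose and tail base.  Frames whose required parts fall below
the likelihood threshold are filled by carrying the last confident
observation forward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IntervalSet, TrackingSeries, ZoneGeometry

LIKELIHOOD_THRESHOLD = 0.9


def _locf(xy: np.ndarray, good: np.ndarray) -> np.ndarray:
    """Last-observation-carried-forward fill of low-likelihood frames."""
    if good.all():
        return xy
    idx = np.where(good, np.arange(len(good)), -1)
    idx = np.maximum.accumulate(idx)
    first = np.argmax(good)  # leading bad frames borrow the first good one
    idx[idx < 0] = first
    return xy[idx]


def _tracked_xy(track: TrackingSeries, part: str) -> np.ndarray:
    good = track.likelihood(part) >= LIKELIHOOD_THRESHOLD
    return _locf(track.xy(part), good)


def body_center_xy(track: TrackingSeries) -> np.ndarray:
    """Midpoint between nose and tail base, per frame."""
    track.require("nose", "tail_base")
    return 0.5 * (_tracked_xy(track, "nose") + _tracked_xy(track, "tail_base"))


def intervals_from_mask(mask: np.ndarray, timestamps: np.ndarray, label: str,
                        session: str) -> IntervalSet:
    """Maximal runs of member frames -> [first_time, last_time + 1/fps)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return IntervalSet(label, session, np.empty((0, 2)))
    dt = float(timestamps[1] - timestamps[0]) if len(timestamps) > 1 else 0.0
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    iv = np.column_stack([timestamps[starts], timestamps[ends - 1] + dt])
    return IntervalSet(label, session, iv)


def compute_zone_intervals(track: TrackingSeries, geom: ZoneGeometry,
                           kind: str, side: str | None = None,
                           chamber_length: float = 45.0) -> IntervalSet:
    """Zone-membership intervals for one session.

    kind='sniff' uses the nose x-coordinate against the 3-cm band at the
    requested face; kind='inzone' uses the nose/tail-base midpoint against
    the 9-cm band; kind='center' uses the midpoint within the middle of the
    five equal sections, ``[2L/5, 3L/5)``.
    """
    if kind == "sniff":
        if side not in ("left", "right"):
            raise ValueError("sniff intervals need side 'left' or 'right'")
        x = _tracked_xy(track, "nose")[:, 0]
        if side == "left":
            mask = x <= geom.sniff_depth
        else:
            mask = x >= chamber_length - geom.sniff_depth
        label = f"sniff_{side}"
    elif kind == "inzone":
        if side not in ("left", "right"):
            raise ValueError("inzone intervals need side 'left' or 'right'")
        x = body_center_xy(track)[:, 0]
        if side == "left":
            mask = x <= geom.inzone_depth
        else:
            mask = x >= chamber_length - geom.inzone_depth
        label = f"inzone_{side}"
    elif kind == "center":
        x = body_center_xy(track)[:, 0]
        lo = 2.0 * geom.section_length
        mask = (x >= lo) & (x < lo + geom.section_length)
        label = "center"
    else:
        raise ValueError(f"unknown zone kind {kind!r}")
    return intervals_from_mask(mask, track.timestamps, label, track.session)


def filter_valid_intervals(iv: IntervalSet, min_duration_s: float,
                           min_gap_s: float) -> IntervalSet:
    """Drop short bouts, then bouts too close to the previously retained one.

    Valid sniffing trials use (1 s, 2 s); valid in-zone and center-zone
    trials use (0.5 s, 0.5 s).
    """
    if min_duration_s < 0 or min_gap_s < 0:
        raise ValueError("thresholds must be non-negative")
    kept: list[np.ndarray] = []
    last_end = -np.inf
    for row in iv.intervals:
        start, end = row
        if end - start < min_duration_s:
            continue
        if start - last_end < min_gap_s:
            continue
        kept.append(row)
        last_end = end
    out = np.array(kept).reshape(-1, 2)
    return IntervalSet(iv.label, iv.session, out)


@dataclass
class ProximityResult:
    proximal: IntervalSet
    distal: IntervalSet
    profile_edges: np.ndarray   # distance bin edges, cm
    profile_durations: np.ndarray  # seconds per bin


def compute_proximity_intervals(subject: TrackingSeries, target_kind: str,
                                target, geom: ZoneGeometry,
                                min_duration_s: float = 1.0,
                                profile_bin_cm: float = 0.5,
                                profile_max_cm: float = 46.0) -> ProximityResult:
    """Proximal/distal interaction intervals from nose-to-target distance.

    For a social target the distance is nose-to-nose; for an object it runs
    to the center of the object chamber face (a fixed point).  Valid trials
    require a duration of at least ``min_duration_s``.
    """
    nose = _tracked_xy(subject, "nose")
    if target_kind == "social":
        if not isinstance(target, TrackingSeries):
            raise ValueError("social proximity needs the target's tracking")
        other = _tracked_xy(target, "target_nose"
                            if "target_nose" in target.parts else "nose")
    elif target_kind == "object":
        other = np.asarray(target, dtype=float).reshape(1, 2)
    else:
        raise ValueError(f"unknown target kind {target_kind!r}")
    d = np.hypot(nose[:, 0] - other[..., 0], nose[:, 1] - other[..., 1])

    dt = subject.frame_dt if subject.n_frames > 1 else 0.0
    prox = intervals_from_mask(d < geom.proximal_max, subject.timestamps,
                               "proximal", subject.session)
    dist = intervals_from_mask((d >= geom.proximal_max) & (d < geom.distal_max),
                               subject.timestamps, "distal", subject.session)
    prox = filter_valid_intervals(prox, min_duration_s, 0.0)
    dist = filter_valid_intervals(dist, min_duration_s, 0.0)

    edges = np.arange(0.0, profile_max_cm + profile_bin_cm, profile_bin_cm)
    counts, _ = np.histogram(d, bins=edges)
    return ProximityResult(prox, dist, edges, counts * dt)


def distance_moved(track: TrackingSeries) -> float:
    """Total path length of the body center, cm."""
    if track.n_frames < 2:
        return 0.0
    bc = body_center_xy(track)
    steps = np.hypot(np.diff(bc[:, 0]), np.diff(bc[:, 1]))
    return float(steps.sum())
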