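"""Synthetic experiment generator.

Emulates the linear-chamber social-interaction paradigm: a subject mouse in a
45 x 10 cm corridor with a chamber face at each end, recorded for a 5-min rest
epoch and three 10-min sessions (empty-empty, then two social-object sessions
with sides swapped).  Trajectories are bounded random walks with dwell states
at the two faces, so every target reliably accrues valid sniffing bouts.
Spike trains come from a thinned homogeneous Poisson process whose rate is
``baseline_rate x target_gain`` while the subject occupies a sniffing zone,
with optional post-hoc burst insertion (each spike spawns 1-2 extra spikes at
the intra-burst interval with probability ``burst_propensity``).

The WT/KO presets encode the firing-regime contrasts the downstream analyses
look for: KO units have a higher resting rate, lower burst propensity, and a
smaller fraction of social-modulated units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .behavior import compute_zone_intervals, filter_valid_intervals
from .core import (SESSION_NAMES, SIX_TARGETS, SUBJECT_PARTS, TARGET_PARTS,
                   ExperimentBundle, SessionLayout, TrackingSeries, UnitRecord,
                   UnitSpec, WaveformFeatures, ZoneGeometry)

GAIN_KEYS = ("left_empty", "right_empty", "social", "object")


class OccupancyError(RuntimeError):
    """Raised when a trajectory cannot satisfy the sniffing-occupancy floor."""


@dataclass
class SimulationConfig:
    """Generator settings for one synthetic experiment.

    Rate parameters are in Hz; the modulated-unit fractions partition the
    population into social / object / empty neurons plus an unmodulated
    remainder.  KO presets scale the WT values: resting rate up ~30%, burst
    propensity down ~50%, social-neuron fraction down ~40%.
    """

    n_units: int = 20
    ko_fraction: float = 0.0
    social_neuron_fraction: float = 0.2
    object_neuron_fraction: float = 0.1
    empty_neuron_fraction: float = 0.1
    gain: float = 3.0                   # multiplicative in-zone rate gain
    decreasing_fraction: float = 0.3    # modulated units with gain 1/g instead
    baseline_log_mean: float = float(np.log(2.0))
    baseline_log_sd: float = 0.4
    baseline_min: float = 0.8
    rest_rate_factor: float = 0.8       # rest rate = factor x baseline (WT)
    burst_propensity: float = 0.2       # WT
    intra_burst_isi: float = 0.005
    ko_rest_factor: float = 1.3
    ko_burst_factor: float = 0.5
    ko_social_fraction_factor: float = 0.6
    pinh_fraction: float = 0.06
    tracking_jitter: float = 0.0        # optional Gaussian jitter on coords, cm
    min_sniff_s: float = 20.0           # occupancy floor per target
    max_redraws: int = 20
    layout: SessionLayout = field(default_factory=SessionLayout)
    social_side: dict = field(default_factory=lambda: {"fSO": "left", "sSO": "right"})
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for frac in (self.ko_fraction, self.social_neuron_fraction,
                     self.object_neuron_fraction, self.empty_neuron_fraction,
                     self.decreasing_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

def _simulate_session_track(layout: SessionLayout, session: str, t0: float,
                            duration: float, with_target: bool,
                            target_face_x: float | None, jitter: float,
                            rng: np.random.Generator) -> TrackingSeries:
    """Bounded random walk with face-dwell states, rasterized at fps."""
    n = int(round(duration * layout.fps))
    length = layout.chamber_length

    # Waypoints (t, x) for the body center: alternate face dwells with
    # travels, occasionally pausing in the center.
    t_pts, x_pts = [0.0], [length / 2.0]
    face = 0 if rng.random() < 0.5 else 1
    t = 0.0
    while t < duration + 5.0:
        target_x = rng.uniform(2.8, 3.8) if face == 0 else length - rng.uniform(2.8, 3.8)
        speed = rng.uniform(8.0, 12.0)
        travel = abs(target_x - x_pts[-1]) / speed
        t += travel
        t_pts.append(t)
        x_pts.append(target_x)
        dwell = rng.uniform(2.0, 4.0)
        t += dwell
        t_pts.append(t)
        x_pts.append(target_x)
        if rng.random() < 0.25:  # a deliberate center pause
            cx = rng.uniform(20.0, 25.0)
            travel = abs(cx - target_x) / speed
            t += travel
            t_pts.append(t)
            x_pts.append(cx)
            pause = rng.uniform(0.8, 1.6)
            t += pause
            t_pts.append(t)
            x_pts.append(cx)
        face = 1 - face

    ft = np.arange(n) / layout.fps
    x = np.interp(ft, t_pts, x_pts)

    # Heading: sign of motion while travelling; face the nearer chamber face
    # while dwelling.
    dx = np.gradient(x)
    hx = np.sign(dx)
    still = np.abs(dx) < 1e-6
    hx[still] = np.where(x[still] < length / 2.0, -1.0, 1.0)
    hx[hx == 0] = 1.0

    # Lateral wander: AR(1) around the corridor midline.
    w = rng.normal(0.0, 0.12, n)
    y = layout.chamber_width / 2.0 + lfilter([1.0], [1.0, -0.97], w)
    y = np.clip(y, 1.5, layout.chamber_width - 1.5)

    def part(px: np.ndarray, py: np.ndarray) -> np.ndarray:
        if jitter > 0:
            px = px + rng.normal(0.0, jitter, n)
            py = py + rng.normal(0.0, jitter, n)
        px = np.clip(px, 0.05, length - 0.05)
        py = np.clip(py, 0.05, layout.chamber_width - 0.05)
        return np.column_stack([px, py, np.ones(n)])

    parts = {
        "nose": part(x + 2.0 * hx, y),
        "left_ear": part(x + 0.5 * hx, y + 1.0),
        "right_ear": part(x + 0.5 * hx, y - 1.0),
        "body_center": part(x, y),
        "tail_base": part(x - 2.0 * hx, y),
    }
    if with_target:
        assert target_face_x is not None
        sign = 1.0 if target_face_x == 0.0 else -1.0
        tx = target_face_x + sign * (0.3 + np.abs(rng.normal(0.0, 0.15, n)))
        ty = layout.chamber_width / 2.0 + rng.normal(0.0, 0.3, n)
        parts["target_nose"] = part(tx, ty)
        parts["target_body_center"] = part(tx + sign * 1.0, ty)

    return TrackingSeries(session=session, timestamps=t0 + ft, parts=parts)


def _check_occupancy(tracking: dict[str, TrackingSeries],
                     social_side: dict[str, str], min_sniff_s: float,
                     geom: ZoneGeometry, layout: SessionLayout) -> str | None:
    """Return the name of the first under-sampled target, or None if all OK."""
    for session, side in SIX_TARGETS:
        track = tracking[session]
        if session != "EE":
            actual = social_side[session] if side == "social" else \
                ("right" if social_side[session] == "left" else "left")
        else:
            actual = side
        iv = compute_zone_intervals(track, geom, "sniff", actual,
                                    chamber_length=layout.chamber_length)
        iv = filter_valid_intervals(iv, 1.0, 2.0)
        if iv.total_duration < min_sniff_s:
            return f"{session}/{side}"
    return None


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def frame_occupancy(bundle_tracking: dict[str, TrackingSeries],
                    layout: SessionLayout, social_side: dict[str, str],
                    geom: ZoneGeometry | None = None) -> np.ndarray:
    """Per-frame zone labels over rest + sessions.

    Labels: ``rest``, ``chamber``, or one of the four target names while the
    subject's nose is inside that target's sniffing zone.
    """
    geom = geom or ZoneGeometry()
    n_total = int(round(layout.total_duration * layout.fps))
    labels = np.full(n_total, "chamber", dtype=object)
    labels[: int(round(layout.rest_duration * layout.fps))] = "rest"
    for session, (t0, _) in layout.session_bounds().items():
        track = bundle_tracking[session]
        nose_x = track.xy("nose")[:, 0]
        left = nose_x <= geom.sniff_depth
        right = nose_x >= layout.chamber_length - geom.sniff_depth
        if session == "EE":
            left_label, right_label = "left_empty", "right_empty"
        elif social_side[session] == "left":
            left_label, right_label = "social", "object"
        else:
            left_label, right_label = "object", "social"
        i0 = int(round(t0 * layout.fps))
        idx = i0 + np.arange(track.n_frames)
        labels[idx[left]] = left_label
        labels[idx[right]] = right_label
    return labels


def simulate_unit_spikes(spec: UnitSpec, occupancy: np.ndarray,
                         layout: SessionLayout,
                         seed: int | np.random.Generator) -> np.ndarray:
    """Thinned-Poisson spike train with post-hoc burst insertion.

    The instantaneous rate is ``rest_rate`` in the rest epoch,
    ``baseline_rate`` elsewhere, and ``baseline_rate x target_gains[target]``
    while the occupancy label names a target.  Expected counts over any
    zone-constant span therefore equal rate x duration (times
    ``1 + 1.5 x burst_propensity`` once bursts are inserted).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = len(occupancy)
    expected = int(round(layout.total_duration * layout.fps))
    if n_frames != expected:
        raise ValueError(f"occupancy has {n_frames} frames, expected {expected}")

    rate_of = {"rest": spec.rest_rate, "chamber": spec.baseline_rate}
    for key in GAIN_KEYS:
        rate_of[key] = spec.baseline_rate * spec.target_gains.get(key, 1.0)
    if any(r < 0 for r in rate_of.values()):
        raise ValueError("negative rate")
    frame_rates = np.array([rate_of[lab] for lab in occupancy], dtype=float)

    rmax = frame_rates.max()
    total = layout.total_duration
    if rmax == 0.0:
        return np.empty(0)
    n = rng.poisson(rmax * total)
    t = np.sort(rng.uniform(0.0, total, n))
    frame_idx = np.minimum((t * layout.fps).astype(int), n_frames - 1)
    keep = rng.random(n) < frame_rates[frame_idx] / rmax
    base = t[keep]

    if spec.burst_propensity > 0 and len(base):
        spawn = rng.random(len(base)) < spec.burst_propensity
        n_extra = rng.integers(1, 3, size=len(base))
        isi = spec.intra_burst_isi
        extras = [base[spawn] + isi,
                  base[spawn & (n_extra == 2)] + 2 * isi]
        base = np.concatenate([base] + extras)
        base = np.sort(base[base < total])
    return base


# ---------------------------------------------------------------------------
# Experiment assembly
# ---------------------------------------------------------------------------

def _draw_unit_specs(config: SimulationConfig,
                     rng: np.random.Generator) -> list[UnitSpec]:
    n = config.n_units
    n_ko = int(round(n * config.ko_fraction))
    genotypes = np.array(["KO"] * n_ko + ["WT"] * (n - n_ko))
    rng.shuffle(genotypes)

    specs: list[UnitSpec] = []
    for geno in ("WT", "KO"):
        idx = np.flatnonzero(genotypes == geno)
        ng = len(idx)
        if ng == 0:
            continue
        social_frac = config.social_neuron_fraction
        if geno == "KO":
            social_frac *= config.ko_social_fraction_factor
        n_social = int(round(ng * social_frac))
        n_object = int(round(ng * config.object_neuron_fraction))
        n_empty = int(round(ng * config.empty_neuron_fraction))
        roles = (["social"] * n_social + ["object"] * n_object +
                 ["empty"] * n_empty)
        roles += ["none"] * (ng - len(roles))
        roles = roles[:ng]
        for role in roles:
            baseline = max(config.baseline_min,
                           float(rng.lognormal(config.baseline_log_mean,
                                               config.baseline_log_sd)))
            rest = baseline * config.rest_rate_factor
            burst = config.burst_propensity
            if geno == "KO":
                rest *= config.ko_rest_factor
                burst *= config.ko_burst_factor
            gain = config.gain
            if config.gain != 1.0 and rng.random() < config.decreasing_fraction:
                gain = 1.0 / config.gain
            gains = {k: 1.0 for k in GAIN_KEYS}
            if role == "social":
                gains["social"] = gain
            elif role == "object":
                gains["object"] = gain
            elif role == "empty":
                gains["left_empty"] = gains["right_empty"] = gain
            is_pinh = rng.random() < config.pinh_fraction
            if is_pinh:
                hvw = rng.uniform(120.0, 180.0)
                pvr = rng.uniform(0.9, 1.3)
            else:
                hvw = rng.uniform(230.0, 320.0)
                pvr = rng.uniform(1.6, 2.4)
            specs.append(UnitSpec(
                genotype=geno, baseline_rate=baseline, rest_rate=rest,
                target_gains=gains, burst_propensity=burst,
                hvw=hvw, pvr=pvr,
                isolation_distance=rng.uniform(30.0, 60.0),
                l_ratio=rng.uniform(0.01, 0.08),
                is_social_neuron=(role == "social"),
                intra_burst_isi=config.intra_burst_isi,
            ))
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


def simulate_experiment(config: SimulationConfig,
                        seed: int | None = None) -> ExperimentBundle:
    """Generate a complete synthetic experiment, deterministically per seed."""
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required")
    layout = config.layout
    rng = np.random.default_rng(seed)
    geom = ZoneGeometry()

    tracking: dict[str, TrackingSeries] = {}
    last_bad = ""
    for attempt in range(config.max_redraws):
        for session, (t0, t1) in layout.session_bounds().items():
            with_target = session != "EE"
            face_x = None
            if with_target:
                face_x = 0.0 if config.social_side[session] == "left" \
                    else layout.chamber_length
            tracking[session] = _simulate_session_track(
                layout, session, t0, t1 - t0, with_target, face_x,
                config.tracking_jitter, rng)
        bad = _check_occupancy(tracking, config.social_side,
                               config.min_sniff_s, geom, layout)
        if bad is None:
            break
        last_bad = bad
    else:
        raise OccupancyError(
            f"target {last_bad} did not accrue {config.min_sniff_s} s of valid "
            f"sniffing after {config.max_redraws} trajectory redraws")

    occupancy = frame_occupancy(tracking, layout, config.social_side, geom)
    specs = _draw_unit_specs(config, rng)

    units: list[UnitRecord] = []
    truth: dict[str, UnitSpec] = {}
    for i, spec in enumerate(specs):
        unit_id = f"u{i:03d}"
        unit_rng = np.random.default_rng([seed, i])
        spikes = simulate_unit_spikes(spec, occupancy, layout, unit_rng)
        units.append(UnitRecord(
            unit_id=unit_id, spikes=spikes,
            features=WaveformFeatures(hvw=spec.hvw, pvr=spec.pvr),
            isolation_distance=spec.isolation_distance,
            l_ratio=spec.l_ratio))
        truth[unit_id] = spec

    return ExperimentBundle(layout=layout, tracking=tracking, units=units,
                            truth=truth, seed=seed,
                            social_side=dict(config.social_side))


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------

def _tracking_frame(track: TrackingSeries) -> pd.DataFrame:
    order = [p for p in SUBJECT_PARTS + TARGET_PARTS if p in track.parts]
    cols, data = [], []
    for part in order:
        for j, coord in enumerate(("x", "y", "likelihood")):
            cols.append(("synthetic", part, coord))
            data.append(track.parts[part][:, j])
    df = pd.DataFrame(np.column_stack(data))
    df.columns = pd.MultiIndex.from_tuples(cols,
                                           names=["scorer", "bodyparts", "coords"])
    return df


def write_experiment(bundle: ExperimentBundle, directory: str | Path) -> None:
    """Write the bundle as DeepLabCut-style tracking CSVs, per-unit spike
    CSVs, a units metadata TSV, a layout file, and a ground-truth TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layout = bundle.layout
    with open(directory / "layout.yaml", "w") as fh:
        yaml.safe_dump({
            "rest_duration": layout.rest_duration,
            "session_durations": list(layout.session_durations),
            "fps": layout.fps,
            "chamber_length": layout.chamber_length,
            "chamber_width": layout.chamber_width,
            "seed": bundle.seed,
            "social_side": bundle.social_side,
        }, fh)

    for session, track in bundle.tracking.items():
        _tracking_frame(track).to_csv(directory / f"tracking_{session}.csv",
                                      float_format="%.17g")

    meta = pd.DataFrame([{
        "unit_id": u.unit_id, "hvw": u.features.hvw, "pvr": u.features.pvr,
        "isolation_distance": u.isolation_distance, "l_ratio": u.l_ratio,
    } for u in bundle.units])
    meta.to_csv(directory / "units.tsv", sep="\t", index=False,
                float_format="%.17g")

    spike_dir = directory / "spikes"
    spike_dir.mkdir(exist_ok=True)
    for u in bundle.units:
        pd.DataFrame({"spike_time_s": u.spikes}).to_csv(
            spike_dir / f"{u.unit_id}.csv", index=False, float_format="%.17g")

    rows = []
    for unit_id, spec in bundle.truth.items():
        row = {"unit_id": unit_id, "genotype": spec.genotype,
               "baseline_rate": spec.baseline_rate, "rest_rate": spec.rest_rate,
               "burst_propensity": spec.burst_propensity,
               "intra_burst_isi": spec.intra_burst_isi,
               "hvw": spec.hvw, "pvr": spec.pvr,
               "isolation_distance": spec.isolation_distance,
               "l_ratio": spec.l_ratio,
               "is_social_neuron": spec.is_social_neuron}
        for key in GAIN_KEYS:
            row[f"gain_{key}"] = spec.target_gains.get(key, 1.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "truth.tsv", sep="\t", index=False,
                              float_format="%.17g")


def read_tracking_csv(path: str | Path, session: str, t0: float,
                      fps: float) -> TrackingSeries:
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                     float_precision="round_trip")
    parts: dict[str, np.ndarray] = {}
    for part in df.columns.get_level_values("bodyparts").unique():
        sub = df.xs(part, axis=1, level="bodyparts")
        sub = sub.droplevel("scorer", axis=1)
        parts[part] = sub[["x", "y", "likelihood"]].to_numpy(dtype=float)
    n = len(df)
    return TrackingSeries(session=session, timestamps=t0 + np.arange(n) / fps,
                          parts=parts)


def read_experiment(directory: str | Path) -> ExperimentBundle:
    """Read back a bundle written by :func:`write_experiment`."""
    directory = Path(directory)
    with open(directory / "layout.yaml") as fh:
        cfg = yaml.safe_load(fh)
    layout = SessionLayout(
        rest_duration=cfg["rest_duration"],
        session_durations=tuple(cfg["session_durations"]),
        fps=cfg["fps"], chamber_length=cfg["chamber_length"],
        chamber_width=cfg["chamber_width"])

    tracking = {}
    for session, (t0, _) in layout.session_bounds().items():
        tracking[session] = read_tracking_csv(
            directory / f"tracking_{session}.csv", session, t0, layout.fps)

    meta = pd.read_csv(directory / "units.tsv", sep="\t",
                       float_precision="round_trip")
    units = []
    for _, row in meta.iterrows():
        spikes = pd.read_csv(directory / "spikes" / f"{row.unit_id}.csv",
                             float_precision="round_trip")
        units.append(UnitRecord(
            unit_id=row.unit_id,
            spikes=spikes["spike_time_s"].to_numpy(dtype=float),
            features=WaveformFeatures(hvw=row.hvw, pvr=row.pvr),
            isolation_distance=row.isolation_distance, l_ratio=row.l_ratio))

    truth = {}
    truth_df = pd.read_csv(directory / "truth.tsv", sep="\t",
                           float_precision="round_trip")
    for _, row in truth_df.iterrows():
        truth[row.unit_id] = UnitSpec(
            genotype=row.genotype, baseline_rate=row.baseline_rate,
            rest_rate=row.rest_rate,
            target_gains={k: row[f"gain_{k}"] for k in GAIN_KEYS},
            burst_propensity=row.burst_propensity,
            intra_burst_isi=row.intra_burst_isi,
            hvw=row.hvw, pvr=row.pvr,
            isolation_distance=row.isolation_distance, l_ratio=row.l_ratio,
            is_social_neuron=bool(row.is_social_neuron))

    return ExperimentBundle(layout=layout, tracking=tracking, units=units,
                            truth=truth, seed=cfg["seed"],
                            social_side=dict(cfg["social_side"]))
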