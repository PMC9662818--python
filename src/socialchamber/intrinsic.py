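"""Current-clamp intrinsic-property extraction with a parametric simulator.

Extracts, from 500-ms square current steps (-300..400 pA in 50-pA
increments), the F-I curve, per-AP features (voltage threshold at the first
upward 5 mV/ms crossing of dV/dt, amplitude, afterhyperpolarization,
full-width at half maximum), the input resistance from the -100 pA sweep,
and per-step burst proportions (ISIs <= 10 ms).  A stereotyped-waveform
simulator generates sweeps whose generator parameters the extraction
recovers, serving as the module's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .bursts import burst_proportion


@dataclass
class SweepSet:
    dt: float                       # s per sample
    step_window: tuple[float, float]  # [onset, offset) of the injection, s
    currents: np.ndarray            # pA, strictly increasing
    traces: np.ndarray              # (n_currents, n_samples) membrane mV

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        self.traces = np.asarray(self.traces, dtype=float)
        if np.any(np.diff(self.currents) <= 0):
            raise ValueError("currents must be strictly increasing")
        if self.traces.shape[0] != len(self.currents):
            raise ValueError("one trace per current required")

    def trace_for(self, current_pa: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.currents, current_pa))
        if len(idx) == 0:
            raise ValueError(f"no sweep at {current_pa} pA")
        return self.traces[idx[0]]


@dataclass
class APFeatures:
    threshold_mV: float
    amplitude_mV: float
    ahp_amplitude_mV: float
    fwhm_ms: float
    peak_time_s: float


def _interp_crossing(x0: float, x1: float, y0: float, y1: float,
                     level: float) -> float:
    return x0 + (level - y0) / (y1 - y0) * (x1 - x0)


def detect_spikes_and_features(trace: np.ndarray, dt: float,
                               dvdt_threshold: float = 5.0,
                               peak_min_mV: float = 0.0,
                               threshold_search_ms: float = 10.0,
                               ahp_window_ms: float = 20.0,
                               ) -> list[APFeatures]:
    """Per-AP features from one sweep.

    Threshold is the membrane potential at the first upward crossing of
    dV/dt = 5 mV/ms preceding each peak (central differences, linear
    interpolation); amplitude and AHP amplitude are the positive and
    negative excursions from that threshold; FWHM is the width at threshold
    + amplitude/2.  Peaks with no crossing in the search window are
    discarded.
    """
    if dt > 1e-4 + 1e-12:
        raise ValueError("dt must be <= 0.1 ms for derivative fidelity")
    v = np.asarray(trace, dtype=float)
    dvdt = np.gradient(v) / (dt * 1000.0)  # mV/ms
    min_sep = max(1, int(0.002 / dt))
    peaks, _ = find_peaks(v, height=peak_min_mV, distance=min_sep)
    search = int(threshold_search_ms / 1000.0 / dt)
    ahp_n = int(ahp_window_ms / 1000.0 / dt)

    out: list[APFeatures] = []
    for k, p in enumerate(peaks):
        lo = max(1, p - search)
        seg = dvdt[lo:p + 1]
        up = np.flatnonzero((seg[1:] >= dvdt_threshold)
                            & (seg[:-1] < dvdt_threshold))
        if len(up) == 0:
            continue  # no crossing before this peak
        i = lo + up[-1]  # last upward crossing preceding the peak
        t_cross = _interp_crossing(i, i + 1, dvdt[i], dvdt[i + 1],
                                   dvdt_threshold)
        thr = float(np.interp(t_cross, [i, i + 1], [v[i], v[i + 1]]))
        amp = float(v[p] - thr)
        if amp <= 0:
            continue

        hi = min(len(v), p + ahp_n)
        if k + 1 < len(peaks):
            hi = min(hi, peaks[k + 1])
        trough = float(v[p:hi].min()) if hi > p else thr
        ahp = thr - trough

        half = thr + amp / 2.0
        left = p
        while left > 0 and v[left - 1] >= half:
            left -= 1
        t_up = _interp_crossing(left - 1, left, v[left - 1], v[left], half) \
            if left > 0 else float(left)
        right = p
        while right < len(v) - 1 and v[right + 1] >= half:
            right += 1
        t_dn = _interp_crossing(right, right + 1, v[right], v[right + 1], half) \
            if right < len(v) - 1 else float(right)
        out.append(APFeatures(thr, amp, float(ahp),
                              float((t_dn - t_up) * dt * 1000.0),
                              float(p * dt)))
    return out


def input_resistance(sweeps: SweepSet, test_current_pa: float = -100.0) -> float:
    """R_in (MOhm) = |steady-state - baseline| / |I|, with baseline the mean
    pre-step potential and steady state the mean over the final 100 ms of
    the step."""
    v = sweeps.trace_for(test_current_pa)
    on, off = sweeps.step_window
    i_on, i_off = int(round(on / sweeps.dt)), int(round(off / sweeps.dt))
    baseline = float(v[:i_on].mean())
    i_tail = i_off - int(round(0.1 / sweeps.dt))
    steady = float(v[i_tail:i_off].mean())
    return abs(steady - baseline) / (abs(test_current_pa) / 1000.0)


def fi_and_burst_curves(sweeps: SweepSet,
                        burst_threshold_ms: float = 10.0) -> pd.DataFrame:
    """Per-current mean evoked firing rate (AP count / step duration) and
    burst proportion; sweeps without APs read 0 Hz and 0% by convention."""
    on, off = sweeps.step_window
    dur = off - on
    rows = []
    for current, trace in zip(sweeps.currents, sweeps.traces):
        feats = detect_spikes_and_features(trace, sweeps.dt)
        times = np.array([f.peak_time_s for f in feats])
        times = times[(times >= on) & (times < off)]
        if len(times):
            prop = burst_proportion(times, burst_threshold_ms).burst_proportion
        else:
            prop = 0.0
        rows.append({"current_pa": current, "n_spikes": len(times),
                     "rate_hz": len(times) / dur,
                     "burst_proportion": prop})
    return pd.DataFrame(rows)


@dataclass
class IntrinsicParams:
    """Generator parameters for the stereotyped-sweep simulator."""

    r_mohm: float = 150.0
    tau_s: float = 0.020
    v_rest: float = -70.0
    threshold_mV: float = -40.0
    amplitude_mV: float = 80.0
    fwhm_ms: float = 1.0
    ahp_mV: float = 10.0
    fi_gain_hz_per_pa: float = 0.08
    rheobase_pa: float = 100.0
    burstiness: float = 0.0
    adaptation: float = 0.1
    dt: float = 1e-4
    pre_s: float = 0.1
    step_s: float = 0.5
    post_s: float = 0.2
    currents_pa: np.ndarray = field(
        default_factory=lambda: np.arange(-300.0, 401.0, 50.0))

    def __post_init__(self) -> None:
        if min(self.r_mohm, self.tau_s, self.amplitude_mV, self.fwhm_ms,
               self.ahp_mV, self.dt) <= 0:
            raise ValueError("physical parameters must be positive")
        if self.dt > 1e-4 + 1e-12:
            raise ValueError("dt too coarse for feature extraction")


def _spike_times(params: IntrinsicParams, current_pa: float,
                 rng: np.random.Generator) -> np.ndarray:
    rate = params.fi_gain_hz_per_pa * (current_pa - params.rheobase_pa)
    n = int(round(max(0.0, rate) * params.step_s))
    if n == 0:
        return np.empty(0)
    on = params.pre_s
    # keep the final AP's AHP search window inside the step
    first, margin = 0.012, 0.030
    avail = params.step_s - first - margin
    if n == 1:
        times = np.array([on + first + avail / 2.0])
    else:
        w = 1.0 + params.adaptation * np.arange(n - 1)
        pos = np.r_[0.0, np.cumsum(w)]
        times = on + first + avail * pos / pos[-1]
    if params.burstiness > 0:
        doublet = times[rng.random(n) < params.burstiness] + 0.008
        gap_ok = np.array([np.all(np.abs(times - t) > 0.004)
                           for t in doublet], dtype=bool)
        times = np.sort(np.r_[times, doublet[gap_ok]])
    return times


def simulate_sweeps(params: IntrinsicParams,
                    seed: int | None = 0) -> SweepSet:
    """Single-exponential RC subthreshold responses with stereotyped
    triangular APs inserted at rate-plus-adaptation spike times; every
    generator parameter is recoverable by the extraction routines."""
    rng = np.random.default_rng(seed)
    dt = params.dt
    n = int(round((params.pre_s + params.step_s + params.post_s) / dt))
    t = np.arange(n) * dt
    on, off = params.pre_s, params.pre_s + params.step_s
    i_on, i_off = int(round(on / dt)), int(round(off / dt))
    base_clamp = params.threshold_mV - 5.0  # depolarized plateau under APs

    traces = np.empty((len(params.currents_pa), n))
    for row, current in enumerate(params.currents_pa):
        i_na = current / 1000.0
        dv = i_na * params.r_mohm
        v = np.full(n, params.v_rest)
        rise = 1.0 - np.exp(-(t[i_on:i_off] - on) / params.tau_s)
        v[i_on:i_off] = params.v_rest + dv * rise
        spiking = current > params.rheobase_pa
        if spiking:
            v[i_on:i_off] = np.minimum(v[i_on:i_off], base_clamp)

        if spiking:
            thr, amp, ahp = (params.threshold_mV, params.amplitude_mV,
                             params.ahp_mV)
            r_ms = 0.8 * params.fwhm_ms
            f_ms = (params.fwhm_ms - r_ms / 2.0) * 2.0 * (amp + ahp) / amp
            r_n = max(2, int(round(r_ms / 1000.0 / dt)))
            f_n = max(2, int(round(f_ms / 1000.0 / dt)))
            tau_rec = 0.008
            prev_end = i_on
            for t_s in _spike_times(params, current, rng):
                i_s = int(round(t_s / dt))
                pre_n = min(int(0.008 / dt), i_s - prev_end - 2)
                if pre_n < 2 or i_s + r_n + f_n >= i_off:
                    continue
                ramp0 = i_s - pre_n
                v[ramp0:i_s + 1] = np.linspace(v[ramp0], thr, pre_n + 1)
                v[i_s:i_s + r_n + 1] = np.linspace(thr, thr + amp, r_n + 1)
                i_pk = i_s + r_n
                v[i_pk:i_pk + f_n + 1] = np.linspace(thr + amp, thr - ahp,
                                                     f_n + 1)
                i_tr = i_pk + f_n
                rec_t = t[i_tr:i_off] - t[i_tr]
                v[i_tr:i_off] = base_clamp - (base_clamp - (thr - ahp)) * \
                    np.exp(-rec_t / tau_rec)
                prev_end = i_tr
        decay = np.exp(-(t[i_off:] - off) / params.tau_s)
        v[i_off:] = params.v_rest + (v[i_off - 1] - params.v_rest) * decay
        traces[row] = v
    return SweepSet(dt=dt, step_window=(on, off),
                    currents=params.currents_pa, traces=traces)


def read_sweeps_csv(path, step_window: tuple[float, float]) -> SweepSet:
    """Plain tabular sweep format: column 1 is time_s, one column per
    current step labeled by its pA value."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    currents = np.array([float(c) for c in df.columns[1:]])
    order = np.argsort(currents)
    traces = df.iloc[:, 1:].to_numpy(dtype=float).T[order]
    return SweepSet(dt=float(t[1] - t[0]), step_window=step_window,
                    currents=currents[order], traces=traces)


def write_sweeps_csv(sweeps: SweepSet, path) -> None:
    n = sweeps.traces.shape[1]
    df = pd.DataFrame({"time_s": np.arange(n) * sweeps.dt})
    for current, trace in zip(sweeps.currents, sweeps.traces):
        df[f"{current:g}"] = trace
    df.to_csv(path, index=False)
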