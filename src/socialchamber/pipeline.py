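"""End-to-end orchestration, group summaries, and the slope-comparison test.

Ties the modules together: behavioral event extraction per session, unit QC,
auROC/permutation target-neuron classification, SVM decoding, firing-rate
dynamics, and burst statistics, with deterministic seeding throughout and a
content-hashed manifest of every output file.  Also provides the
simple-linear-regression slope comparison (and, for homogeneous slopes, the
elevation test) used for the log sigma-vs-mean genotype contrast, and
neuron-proportion / Venn summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import behavior, bursts, decoding, dynamics, encoding, unitqc
from .core import (CLASS_TARGETS, SESSION_NAMES, SIX_TARGETS, ExperimentBundle,
                   IntervalSet, ZoneGeometry, merge_interval_sets)

log = logging.getLogger("socialchamber")


# ---------------------------------------------------------------------------
# Slope / elevation comparison (ANCOVA-style, two groups)
# ---------------------------------------------------------------------------

@dataclass
class SlopeComparison:
    slope_1: float
    slope_2: float
    slope_diff: float
    t_slope: float
    df_slope: int
    p_slope: float
    common_slope: float | None = None
    intercept_diff: float | None = None
    t_intercept: float | None = None
    df_intercept: int | None = None
    p_intercept: float | None = None


def compare_slopes(x1, y1, x2, y2, alpha: float = 0.05) -> SlopeComparison:
    """Test equality of two regression slopes; if they are homogeneous at
    ``alpha``, additionally test equality of elevations (intercepts) under a
    common slope.

    t_slope = (b1 - b2) / SE with the residual variance pooled over both
    separate fits, df = n1 + n2 - 4; the elevation test uses the common-slope
    model with df = n1 + n2 - 3.
    """
    x1, y1, x2, y2 = (np.asarray(a, dtype=float) for a in (x1, y1, x2, y2))
    n1, n2 = len(x1), len(x2)
    if n1 < 3 or n2 < 3:
        raise ValueError("need at least 3 points per group")

    def moments(x, y):
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        return sxx, sxy, syy

    sxx1, sxy1, syy1 = moments(x1, y1)
    sxx2, sxy2, syy2 = moments(x2, y2)
    if sxx1 <= 0 or sxx2 <= 0:
        raise ValueError("degenerate x (zero variance) in one group")
    b1, b2 = sxy1 / sxx1, sxy2 / sxx2
    ss_res = (syy1 - sxy1 ** 2 / sxx1) + (syy2 - sxy2 ** 2 / sxx2)
    df_s = n1 + n2 - 4
    s2 = ss_res / df_s
    se = np.sqrt(s2 * (1.0 / sxx1 + 1.0 / sxx2))
    t_s = (b1 - b2) / se if se > 0 else 0.0
    p_s = 2.0 * sps.t.sf(abs(t_s), df_s) if se > 0 else 1.0

    result = SlopeComparison(float(b1), float(b2), float(b1 - b2),
                             float(t_s), df_s, float(p_s))
    if p_s >= alpha:
        bc = (sxy1 + sxy2) / (sxx1 + sxx2)
        ss_c = (syy1 + syy2) - (sxy1 + sxy2) ** 2 / (sxx1 + sxx2)
        df_i = n1 + n2 - 3
        s2c = ss_c / df_i
        num = (y1.mean() - y2.mean()) - bc * (x1.mean() - x2.mean())
        den = np.sqrt(s2c * (1.0 / n1 + 1.0 / n2 +
                             (x1.mean() - x2.mean()) ** 2 / (sxx1 + sxx2)))
        t_i = num / den if den > 0 else 0.0
        p_i = 2.0 * sps.t.sf(abs(t_i), df_i) if den > 0 else 1.0
        result.common_slope = float(bc)
        result.intercept_diff = float(num)
        result.t_intercept = float(t_i)
        result.df_intercept = df_i
        result.p_intercept = float(p_i)
    return result


# ---------------------------------------------------------------------------
# Behavioral event tables for one experiment
# ---------------------------------------------------------------------------

@dataclass
class EventTables:
    """Valid behavioral trials of one experiment, keyed by (session, target)."""

    valid_sniff: dict[tuple[str, str], IntervalSet]
    valid_inzone: dict[tuple[str, str], IntervalSet]
    valid_center: dict[str, IntervalSet]

    def pooled_center(self) -> IntervalSet:
        return merge_interval_sets(
            [self.valid_center[s] for s in SESSION_NAMES], "center")

    def pooled_sniff(self, target: str) -> IntervalSet:
        """Classification contexts: empty pools both E-E sides; social and
        object pool their bouts over both S-O sessions."""
        if target == "empty":
            keys = [("EE", "left"), ("EE", "right")]
        elif target in ("social", "object"):
            keys = [("fSO", target), ("sSO", target)]
        else:
            raise ValueError(f"unknown classification target {target!r}")
        return merge_interval_sets([self.valid_sniff[k] for k in keys],
                                   f"sniff_{target}")


def extract_events(bundle: ExperimentBundle,
                   geom: ZoneGeometry | None = None,
                   sniff_valid: tuple[float, float] = (1.0, 2.0),
                   inzone_valid: tuple[float, float] = (0.5, 0.5),
                   ) -> EventTables:
    geom = geom or ZoneGeometry()
    L = bundle.layout.chamber_length
    valid_sniff, valid_inzone, valid_center = {}, {}, {}
    for session, target in SIX_TARGETS:
        side = bundle.target_side(session, target)
        track = bundle.tracking[session]
        sniff = behavior.compute_zone_intervals(track, geom, "sniff", side, L)
        valid_sniff[(session, target)] = behavior.filter_valid_intervals(
            sniff, *sniff_valid)
        inzone = behavior.compute_zone_intervals(track, geom, "inzone", side, L)
        valid_inzone[(session, target)] = behavior.filter_valid_intervals(
            inzone, *inzone_valid)
    for session in SESSION_NAMES:
        center = behavior.compute_zone_intervals(
            bundle.tracking[session], geom, "center", chamber_length=L)
        valid_center[session] = behavior.filter_valid_intervals(
            center, *inzone_valid)
    return EventTables(valid_sniff, valid_inzone, valid_center)


def events_table(events: EventTables) -> pd.DataFrame:
    rows = []
    def emit(session, label, iv):
        for start, end in iv.intervals:
            rows.append({"session": session, "label": label,
                         "start_s": start, "end_s": end})
    for (session, target), iv in events.valid_sniff.items():
        emit(session, f"sniff_{target}", iv)
    for (session, target), iv in events.valid_inzone.items():
        emit(session, f"inzone_{target}", iv)
    for session, iv in events.valid_center.items():
        emit(session, "center", iv)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-experiment analyses
# ---------------------------------------------------------------------------

def classify_all_targets(bundle: ExperimentBundle, events: EventTables,
                         units=None, n_shuffles: int = 1000,
                         min_bins: int = 40) -> pd.DataFrame:
    """auROC/permutation classification of every unit against each of the
    empty, social, and object contexts.  Each unit gets its own generator
    seeded from (experiment seed, unit index) for reproducibility under any
    execution order."""
    units = bundle.units if units is None else units
    center = events.pooled_center()
    sniff = {t: events.pooled_sniff(t) for t in CLASS_TARGETS}
    rows = []
    for i, u in enumerate(bundle.units):
        if u not in units:
            continue
        rng = np.random.default_rng([bundle.seed, 1000 + i])
        for target in CLASS_TARGETS:
            res = encoding.classify_target_neuron(
                u.spikes, sniff[target], center, n_shuffles=n_shuffles,
                min_bins=min_bins, seed=rng, unit_id=u.unit_id, target=target)
            rows.append({
                "unit_id": u.unit_id, "target": target, "auroc": res.auroc,
                "q005": None if res.null_quantiles is None else res.null_quantiles[0],
                "q995": None if res.null_quantiles is None else res.null_quantiles[1],
                "label": res.label, "direction": res.direction})
    return pd.DataFrame(rows)


def decoding_tables(bundle: ExperimentBundle, events: EventTables,
                    session: str, units=None) -> list[decoding.TrialRateTable]:
    """Trial-rate tables for the session's class pair: left/right sniffing
    trials in E-E, social/object in an S-O session."""
    if session == "EE":
        key_a, key_b = ("EE", "left"), ("EE", "right")
    else:
        key_a, key_b = (session, "social"), (session, "object")
    iv_a = events.valid_sniff[key_a].intervals
    iv_b = events.valid_sniff[key_b].intervals
    units = bundle.units if units is None else units
    return [decoding.TrialRateTable(u.unit_id,
                                    decoding.trial_rates(u.spikes, iv_a),
                                    decoding.trial_rates(u.spikes, iv_b))
            for u in units]


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    per_genotype: pd.DataFrame       # counts and percentages
    venn: dict[str, dict[str, int]]  # genotype -> E/S/O region counts
    tables_2x2: dict[str, np.ndarray]  # target -> [[resp, non], [resp, non]]


def proportion_summary(classifications: pd.DataFrame) -> GroupSummary:
    """Counts and percentages per genotype plus E/S/O Venn region counts.

    ``classifications`` needs one row per unit with columns: unit_id,
    genotype, cell_class, and boolean columns empty/social/object marking
    responsive calls.
    """
    df = classifications
    rows, venn, tables = [], {}, {}
    genotypes = sorted(df["genotype"].unique()) if len(df) else []
    for geno in genotypes:
        sub = df[df["genotype"] == geno]
        total = len(sub)
        row = {"genotype": geno, "total": total}
        for cls in ("pExc", "pInh"):
            n = int((sub["cell_class"] == cls).sum())
            row[f"n_{cls}"] = n
            row[f"pct_{cls}"] = 100.0 * n / total if total else 0.0
        for target in CLASS_TARGETS:
            n = int(sub[target].sum()) if target in sub else 0
            row[f"n_{target}"] = n
            row[f"pct_{target}"] = 100.0 * n / total if total else 0.0
        rows.append(row)

        e = sub["empty"].to_numpy(bool) if "empty" in sub else np.zeros(total, bool)
        s = sub["social"].to_numpy(bool) if "social" in sub else np.zeros(total, bool)
        o = sub["object"].to_numpy(bool) if "object" in sub else np.zeros(total, bool)
        venn[geno] = {
            "E": int((e & ~s & ~o).sum()), "S": int((s & ~e & ~o).sum()),
            "O": int((o & ~e & ~s).sum()), "ES": int((e & s & ~o).sum()),
            "EO": int((e & o & ~s).sum()), "SO": int((s & o & ~e).sum()),
            "ESO": int((e & s & o).sum()), "none": int((~e & ~s & ~o).sum()),
        }
    if len(genotypes) == 2:
        for target in CLASS_TARGETS:
            table = np.zeros((2, 2), dtype=int)
            for gi, geno in enumerate(genotypes):
                sub = df[df["genotype"] == geno]
                n_resp = int(sub[target].sum()) if target in sub else 0
                table[gi] = [n_resp, len(sub) - n_resp]
            tables[target] = table
    empty_cols = ["genotype", "total"]
    return GroupSummary(pd.DataFrame(rows, columns=None if rows else empty_cols),
                        venn, tables)


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for an end-to-end run.  Analysis parameters default to
    the study's printed values; the generator block defines the synthetic
    experiment when no input directory is given."""

    seed: int = 0
    out_dir: str | Path = "run_out"
    input_dir: str | Path | None = None
    simulate: "object | None" = None   # SimulationConfig
    geometry: ZoneGeometry = field(default_factory=ZoneGeometry)
    n_shuffles: int = 1000
    min_bins: int = 40
    n_rep: int = 100
    ensemble_sizes: tuple[int, ...] = (1, 5, 10)
    decode_session: str = "fSO"
    burst_threshold_ms: float = 10.0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline and write one TSV per stage plus a
    content-hashed manifest.  Deterministic for a fixed (config, seed)."""
    from . import synthdata  # deferred: synthdata imports behavior

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None:
        log.info("stage load: %s", config.input_dir)
        bundle = synthdata.read_experiment(config.input_dir)
    else:
        sim = config.simulate or synthdata.SimulationConfig()
        log.info("stage simulate: n_units=%d seed=%d", sim.n_units, config.seed)
        bundle = synthdata.simulate_experiment(sim, seed=config.seed)
    layout = bundle.layout

    try:
        log.info("stage behavior")
        events = extract_events(bundle, config.geometry)
        events_table(events).to_csv(out / "events.tsv", sep="\t", index=False)

        log.info("stage unitqc")
        qc = unitqc.qc_report(bundle.units, layout.chamber_epoch,
                              events.valid_sniff, events.valid_inzone)
        qc.to_csv(out / "qc.tsv", sep="\t", index=False)
        included = [u for u in bundle.units if u.included]

        log.info("stage encoding (%d units)", len(included))
        enc = classify_all_targets(bundle, events, included,
                                   config.n_shuffles, config.min_bins)
        enc.to_csv(out / "encoding.tsv", sep="\t", index=False)

        log.info("stage decoding")
        tables = decoding_tables(bundle, events, config.decode_session, included)
        rows = []
        rng = np.random.default_rng([config.seed, 424242])
        eligible = [t for t in tables if t.eligible()]
        for size in config.ensemble_sizes:
            if size > len(eligible):
                continue
            for shuffled in (False, True):
                res = decoding.population_decoding(
                    eligible, size, n_rep=config.n_rep, shuffled=shuffled,
                    seed=rng)
                for rep, acc in enumerate(res.accuracies):
                    rows.append({"scope": "ensemble", "ensemble_size": size,
                                 "repetition": rep, "accuracy": acc,
                                 "shuffled": shuffled})
        pd.DataFrame(rows).to_csv(out / "decoding.tsv", sep="\t", index=False)

        log.info("stage dynamics")
        dyn_rows, maxdelta_rows = [], []
        bounds = layout.session_bounds()
        for u in included:
            series = dynamics.instantaneous_rates(u.spikes, layout.chamber_epoch)
            summ = dynamics.summarize_dynamics(series, layout.chamber_epoch,
                                               bounds)
            row = {"unit_id": u.unit_id, "mean": summ.mean_rate,
                   "max": summ.max_rate, "min": summ.min_rate,
                   "range": summ.fr_range, "sigma": summ.sigma}
            for name, s in summ.per_session.items():
                row[f"sigma_{name}"] = s.sigma
                row[f"range_{name}"] = s.fr_range
            dyn_rows.append(row)
            for session in SESSION_NAMES:
                if session == "EE":
                    k1, k2 = ("EE", "left"), ("EE", "right")
                else:
                    k1, k2 = (session, "social"), (session, "object")
                try:
                    md = dynamics.max_delta_fr(
                        u.spikes, events.valid_inzone[k1],
                        events.valid_inzone[k2], events.valid_center[session])
                except ValueError:
                    continue
                maxdelta_rows.append({
                    "unit_id": u.unit_id, "session": session,
                    "fr_c": md.fr_c, "fr_i1": md.fr_i1, "fr_i2": md.fr_i2,
                    "max_delta": md.max_delta,
                    "normalized_max_delta": md.normalized_max_delta})
        pd.DataFrame(dyn_rows).to_csv(out / "dynamics.tsv", sep="\t", index=False)
        pd.DataFrame(maxdelta_rows).to_csv(out / "maxdelta.tsv", sep="\t",
                                           index=False)

        log.info("stage bursts")
        burst_rows = []
        rest = (0.0, layout.rest_duration)
        for u in included:
            per_epoch = bursts.burst_rest_vs_chamber(
                u.spikes, rest, layout.chamber_epoch,
                [config.burst_threshold_ms])
            for epoch, by_thr in per_epoch.items():
                for thr, st in by_thr.items():
                    burst_rows.append({
                        "unit_id": u.unit_id, "epoch": epoch,
                        "threshold_ms": thr, "n_burst": st.n_burst_spikes,
                        "n_total": st.n_total_spikes,
                        "proportion": st.burst_proportion})
        pd.DataFrame(burst_rows).to_csv(out / "bursts.tsv", sep="\t", index=False)

        log.info("stage summary")
        resp = enc[enc["label"] == "responsive"]
        unit_rows = []
        for u in bundle.units:
            row = {"unit_id": u.unit_id,
                   "genotype": bundle.truth[u.unit_id].genotype
                   if u.unit_id in bundle.truth else "NA",
                   "cell_class": u.cell_class}
            for target in CLASS_TARGETS:
                row[target] = bool(
                    ((resp["unit_id"] == u.unit_id)
                     & (resp["target"] == target)).any())
            unit_rows.append(row)
        summary = proportion_summary(pd.DataFrame(unit_rows))
        summary.per_genotype.to_csv(out / "summary.tsv", sep="\t", index=False)
        with open(out / "venn.json", "w") as fh:
            json.dump(summary.venn, fh, indent=1)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                if p.is_file() and p.name != "manifest.json"}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
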