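"""Single-unit and pseudo-population SVM decoding of target identity.

Decodes left-vs-right (E-E session) or social-vs-object (S-O sessions) from
trial firing rates with a linear SVM and leave-one-out cross-validation:
10 trials are sampled per class, each fold holds out the i-th trial of each
class, trains on the remaining 18, and tests the 2 held-out trials.  The
procedure repeats 100 times and reports the mean accuracy (%).  A
label-shuffle control permutes class labels within each repetition's 20
selected trials and should sit at the 50% chance level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC


@dataclass
class TrialRateTable:
    """Per-trial firing rates (Hz) of one unit for the two decoded classes."""

    unit_id: str
    class_a_rates: np.ndarray
    class_b_rates: np.ndarray

    def __post_init__(self) -> None:
        self.class_a_rates = np.asarray(self.class_a_rates, dtype=float)
        self.class_b_rates = np.asarray(self.class_b_rates, dtype=float)

    def eligible(self, min_trials: int = 10) -> bool:
        return (len(self.class_a_rates) >= min_trials
                and len(self.class_b_rates) >= min_trials)


@dataclass
class DecodingResult:
    scope: str                 # 'single_unit' or 'ensemble'
    ensemble_size: int
    accuracies: np.ndarray     # percent, one per repetition
    shuffled: bool

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def trial_rates(spikes: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Rate per trial: spikes in the trial divided by the trial duration."""
    spikes = np.asarray(spikes, dtype=float)
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    lo = np.searchsorted(spikes, iv[:, 0])
    hi = np.searchsorted(spikes, iv[:, 1])
    return (hi - lo) / (iv[:, 1] - iv[:, 0])


def _loo_accuracy(xa: np.ndarray, xb: np.ndarray,
                  rng: np.random.Generator, shuffled: bool,
                  n_trials: int, C: float) -> float:
    """One repetition: leave-one-out over paired trials; percent correct.

    The shuffle control permutes class labels over the repetition's 20
    selected trials (re-partitioning them into two balanced pseudo-groups,
    so every fold still trains on 9 + 9).  Ambiguous predictions (decision
    value exactly 0) count as incorrect.
    """
    X = np.vstack([xa, xb])
    y = np.r_[np.zeros(n_trials), np.ones(n_trials)]
    if shuffled:
        X = X[rng.permutation(2 * n_trials)]
    correct = 0
    for i in range(n_trials):
        test = np.array([i, n_trials + i])
        train = np.setdiff1d(np.arange(2 * n_trials), test)
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[train], y[train])
        dec = clf.decision_function(X[test])
        pred = np.where(dec > 0, clf.classes_[1], clf.classes_[0])
        correct += int(np.sum((pred == y[test]) & (dec != 0)))
    return 100.0 * correct / (2 * n_trials)


def single_unit_decoding(table: TrialRateTable, n_rep: int = 100,
                         shuffled: bool = False,
                         seed: int | np.random.Generator | None = None,
                         n_trials: int = 10, C: float = 1.0) -> DecodingResult:
    """Leave-one-out SVM decoding from one unit's trial rates."""
    if not table.eligible(n_trials):
        raise ValueError(
            f"unit {table.unit_id}: needs >= {n_trials} trials per class")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    acc = np.empty(n_rep)
    for r in range(n_rep):
        ia = rng.choice(len(table.class_a_rates), n_trials, replace=False)
        ib = rng.choice(len(table.class_b_rates), n_trials, replace=False)
        acc[r] = _loo_accuracy(table.class_a_rates[ia][:, None],
                               table.class_b_rates[ib][:, None],
                               rng, shuffled, n_trials, C)
    return DecodingResult("single_unit", 1, acc, shuffled)


def population_decoding(tables: Sequence[TrialRateTable], ensemble_size: int,
                        n_rep: int = 100, shuffled: bool = False,
                        seed: int | np.random.Generator | None = None,
                        n_trials: int = 10, C: float = 1.0) -> DecodingResult:
    """Pseudo-population decoding: per repetition, sample ``ensemble_size``
    units, independently sample 10 trials per class per unit, and pair the
    i-th sampled trial of every unit into one feature vector."""
    eligible = [t for t in tables if t.eligible(n_trials)]
    if ensemble_size < 1 or ensemble_size > len(eligible):
        raise ValueError(
            f"ensemble_size must be in [1, {len(eligible)}] eligible units")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    acc = np.empty(n_rep)
    for r in range(n_rep):
        chosen = rng.choice(len(eligible), ensemble_size, replace=False)
        xa = np.empty((n_trials, ensemble_size))
        xb = np.empty((n_trials, ensemble_size))
        for j, k in enumerate(chosen):
            t = eligible[k]
            xa[:, j] = t.class_a_rates[
                rng.choice(len(t.class_a_rates), n_trials, replace=False)]
            xb[:, j] = t.class_b_rates[
                rng.choice(len(t.class_b_rates), n_trials, replace=False)]
        acc[r] = _loo_accuracy(xa, xb, rng, shuffled, n_trials, C)
    return DecodingResult("ensemble", ensemble_size, acc, shuffled)


def correct_neuron_flag(result: DecodingResult,
                        threshold: float = 55.0) -> bool:
    """'Correct neuron': single-unit mean decoding accuracy strictly above
    the 55% mark."""
    if result.scope != "single_unit":
        raise ValueError("correct_neuron_flag applies to single-unit results")
    return result.mean_accuracy > threshold
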