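"""auROC computation, permutation classification, SDFs, z-scores."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from socialchamber import encoding
from socialchamber.core import IntervalSet


def rank_auc(a, b):
    """Exhaustive rank-statistic oracle: P(a > b) + 0.5 P(a = b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    gt = (a[:, None] > b[None, :]).mean()
    eq = (a[:, None] == b[None, :]).mean()
    return gt + 0.5 * eq


class TestBinnedRates:
    def test_trailing_remainder_dropped(self):
        iv = IntervalSet("s", "EE", [(0.0, 2.2)])
        rates = encoding.binned_rates([], iv)
        assert len(rates) == 4

    def test_four_spikes_in_half_second_bin(self):
        iv = IntervalSet("s", "EE", [(0.0, 0.5)])
        rates = encoding.binned_rates([0.1, 0.2, 0.3, 0.4], iv)
        np.testing.assert_allclose(rates, [8.0])

    def test_no_spikes_all_zero(self):
        iv = IntervalSet("s", "EE", [(0.0, 3.0), (5.0, 6.0)])
        rates = encoding.binned_rates([], iv)
        assert len(rates) == 8 and not rates.any()

    def test_empty_intervals_empty_samples(self):
        assert len(encoding.binned_rates([1.0], IntervalSet("s", "EE", []))) == 0


class TestAuroc:
    def test_perfect_separation(self):
        assert encoding.auroc([2.0] * 5, [1.0] * 5) == pytest.approx(1.0)

    def test_identical_samples_give_half(self):
        assert encoding.auroc([1, 2, 3.0], [1, 2, 3.0]) == pytest.approx(0.5)

    def test_pairwise_oracle_example(self):
        # 16 ordered pairs: 3 wins + 3 ties -> (3 + 1.5) / 16
        assert rank_auc([0, 1, 2, 3], [1, 2, 3, 4]) == 0.28125
        assert encoding.auroc([0, 1, 2, 3], [1, 2, 3, 4]) == \
            pytest.approx(0.28125, abs=0.01)

    def test_sweep_matches_rank_oracle_on_continuous_data(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(40, 150))
            b = rng.normal(rng.uniform(-1, 1), 1, rng.integers(40, 150))
            assert abs(encoding.auroc(a, b) - rank_auc(a, b)) <= 0.01

    def test_complement_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.gamma(2, 1, 60), rng.gamma(3, 1, 80)
        assert encoding.auroc(a, b) + encoding.auroc(b, a) == \
            pytest.approx(1.0, abs=0.01)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1, 1, 70), rng.normal(0, 1, 70)
        raw = encoding.auroc(a, b)
        warped = encoding.auroc(np.exp(a), np.exp(b))
        assert warped == pytest.approx(raw, abs=0.01)

    def test_agrees_with_sklearn_rank_auc(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0.5, 1, 90), rng.normal(0, 1, 110)
        ref = roc_auc_score(np.r_[np.ones(90), np.zeros(110)], np.r_[a, b])
        assert encoding.auroc(a, b) == pytest.approx(ref, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            encoding.auroc([], [1.0])


def spikes_at_rate(rate, iv, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for s, e in iv.intervals:
        n = rng.poisson(rate * (e - s))
        out.append(rng.uniform(s, e, n))
    return np.sort(np.concatenate(out)) if out else np.empty(0)


class TestClassification:
    def _ivs(self, n_sniff=60, n_center=60):
        sniff = IntervalSet("sniff", "fSO",
                            [(10.0 * i, 10.0 * i + 0.5) for i in range(n_sniff)])
        off = 10.0 * n_sniff + 100
        center = IntervalSet("center", "fSO",
                             [(off + 10.0 * i, off + 10.0 * i + 0.5)
                              for i in range(n_center)])
        return sniff, center

    def test_extreme_separation_is_increasing_responsive(self):
        sniff, center = self._ivs()
        spikes = np.sort(np.r_[spikes_at_rate(10.0, sniff, 1),
                               spikes_at_rate(1.0, center, 2)])
        res = encoding.classify_target_neuron(spikes, sniff, center, seed=0)
        assert res.label == "responsive"
        assert res.direction == "increasing"
        assert res.auroc > res.null_quantiles[1]

    def test_suppression_is_decreasing_responsive(self):
        sniff, center = self._ivs()
        spikes = np.sort(np.r_[spikes_at_rate(0.5, sniff, 1),
                               spikes_at_rate(8.0, center, 2)])
        res = encoding.classify_target_neuron(spikes, sniff, center, seed=0)
        assert res.label == "responsive" and res.direction == "decreasing"

    def test_too_few_center_bins_is_insufficient(self):
        sniff, center = self._ivs(n_center=39)
        spikes = spikes_at_rate(5.0, sniff, 0)
        res = encoding.classify_target_neuron(spikes, sniff, center, seed=0)
        assert res.label == "insufficient_data" and res.direction == "n/a"

    def test_seeded_determinism(self):
        sniff, center = self._ivs()
        spikes = np.sort(np.r_[spikes_at_rate(3.0, sniff, 1),
                               spikes_at_rate(2.0, center, 2)])
        a = encoding.classify_target_neuron(spikes, sniff, center, seed=42)
        b = encoding.classify_target_neuron(spikes, sniff, center, seed=42)
        assert a.null_quantiles == b.null_quantiles and a.label == b.label

    def test_invalid_shuffle_count(self):
        sniff, center = self._ivs()
        with pytest.raises(ValueError):
            encoding.classify_target_neuron([], sniff, center, n_shuffles=0)


class TestSDF:
    def test_single_spike_lands_in_one_bin(self):
        sdf = encoding.spike_density_function([10.1], [10.0])
        assert len(sdf) == 18
        assert sdf[6] == pytest.approx(4.0)  # bin [0, 0.25) after onset
        assert np.delete(sdf, 6).sum() == 0

    def test_two_identical_trials_average_to_single(self):
        spikes = np.sort(np.r_[10.0 + np.array([0.1, 0.4, 1.0]),
                               50.0 + np.array([0.1, 0.4, 1.0])])
        one = encoding.spike_density_function(spikes, [10.0])
        two = encoding.spike_density_function(spikes, [10.0, 50.0])
        np.testing.assert_allclose(one, two)

    def test_normalization_joint_max_is_one(self):
        sdfs = {"empty": np.array([0.5, 1.0]), "social": np.array([2.0, 4.0]),
                "object": np.array([0.0, 1.0])}
        normed = encoding.normalize_sdfs(sdfs)
        assert max(v.max() for v in normed.values()) == pytest.approx(1.0)
        np.testing.assert_allclose(normed["social"], [0.5, 1.0])
        np.testing.assert_allclose(normed["empty"], [0.125, 0.25])


class TestZScores:
    @pytest.mark.parametrize("fr,mu,sd,z", [
        (5.0, 3.0, 1.0, 2.0), (3.0, 3.0, 1.0, 0.0), (1.0, 3.0, 2.0, -1.0)])
    def test_zscore_formula(self, fr, mu, sd, z):
        iv = IntervalSet("t", "fSO", [(0.0, 10.0)])
        spikes = np.linspace(0.0, 9.999, int(fr * 10))
        stats = encoding.CenterStats(mu, sd, 100)
        assert encoding.target_zscore(spikes, iv, stats) == pytest.approx(z)

    def test_degenerate_center_rejected(self):
        iv = IntervalSet("t", "fSO", [(0.0, 1.0)])
        with pytest.raises(ValueError):
            encoding.target_zscore([0.5], iv, encoding.CenterStats(1.0, 0.0, 50))

    @pytest.mark.parametrize("z,direction,expected", [
        ([0.5, -0.2, 1.1, 0.3], "increasing", 75.0),
        ([1.0, 2.0, 0.1], "increasing", 100.0),
        ([-1.0, -1.0], "decreasing", 100.0),
        ([0.0, 1.0], "increasing", 50.0),  # exact zero counts against
    ])
    def test_trial_consistency(self, z, direction, expected):
        assert encoding.trial_consistency(z, direction) == pytest.approx(expected)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            encoding.trial_consistency([], "increasing")


class TestOnSyntheticUnits:
    def test_increasing_units_have_positive_mean_trial_z(self, small_bundle,
                                                         small_events):
        center = small_events.pooled_center()
        sniff = small_events.pooled_sniff("social")
        checked = 0
        for i, u in enumerate(small_bundle.units):
            res = encoding.classify_target_neuron(
                u.spikes, sniff, center, seed=np.random.default_rng([2, i]))
            if res.label != "responsive":
                continue
            stats = encoding.compute_center_stats(u.spikes, center)
            z = encoding.per_trial_zscores(u.spikes, sniff, stats)
            if res.direction == "increasing":
                assert z.mean() > 0
            else:
                assert z.mean() < 0
            checked += 1
        assert checked >= 3

    def test_cross_session_zscores_correlate(self, small_bundle, small_events):
        """A target-modulated unit responds consistently in both S-O
        sessions: per-unit z-scores correlate positively across units."""
        center = small_events.pooled_center()
        z1, z2 = [], []
        for u in small_bundle.units:
            stats = encoding.compute_center_stats(u.spikes, center)
            if stats.sigma_c <= 0:
                continue
            z1.append(encoding.target_zscore(
                u.spikes, small_events.valid_sniff[("fSO", "social")], stats))
            z2.append(encoding.target_zscore(
                u.spikes, small_events.valid_sniff[("sSO", "social")], stats))
        assert np.corrcoef(z1, z2)[0, 1] > 0.5
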