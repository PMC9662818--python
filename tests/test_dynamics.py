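"""Sliding-window rate series, sigma/range, histograms, max-delta rates."""

import numpy as np
import pytest

from socialchamber import dynamics
from socialchamber.core import IntervalSet


class TestInstantaneousRates:
    def test_uniform_train_reads_its_rate(self):
        spikes = np.arange(0.25, 60.0, 0.5)
        series = dynamics.instantaneous_rates(spikes, (0.0, 60.0))
        np.testing.assert_allclose(series[:-3], 2.0)  # full 3-s windows

    def test_thirty_minutes_gives_1800_windows(self):
        series = dynamics.instantaneous_rates([], (300.0, 2100.0))
        assert len(series) == 1800

    def test_final_window_truncated_to_one_second(self):
        spikes = np.array([9.1, 9.5, 9.9])
        series = dynamics.instantaneous_rates(spikes, (0.0, 10.0))
        assert len(series) == 10
        assert series[-1] == pytest.approx(3.0)  # 3 spikes / 1 s

    def test_alternate_window_sizes_supported(self):
        spikes = np.arange(0.1, 10.0, 0.1)
        for w in (0.5, 1.0, 5.0):
            series = dynamics.instantaneous_rates(spikes, (0.0, 10.0),
                                                  window_s=w)
            assert len(series) == 10

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            dynamics.instantaneous_rates([], (0.0, 10.0), window_s=0.0)

    def test_brute_force_equality(self):
        """Module output equals a literal re-count from raw spike times."""
        rng = np.random.default_rng(5)
        spikes = np.sort(rng.uniform(100.0, 400.0, 600))
        series = dynamics.instantaneous_rates(spikes, (100.0, 400.0))
        brute = []
        for k in range(300):
            lo, hi = 100.0 + k, min(100.0 + k + 3.0, 400.0)
            brute.append(np.sum((spikes >= lo) & (spikes < hi)) / (hi - lo))
        np.testing.assert_array_equal(series, brute)


class TestSummary:
    def test_range_and_sample_sd(self):
        s = dynamics.summarize_dynamics(np.array([1.0, 1.0, 3.0]), (0.0, 3.0))
        assert s.fr_range == pytest.approx(2.0)
        assert s.sigma == pytest.approx(1.1547, abs=1e-4)

    def test_constant_series(self):
        s = dynamics.summarize_dynamics(np.full(100, 2.0), (0.0, 100.0))
        assert s.sigma == 0.0 and s.fr_range == 0.0

    def test_per_session_split_uses_window_starts(self):
        values = np.r_[np.ones(10), np.full(10, 3.0)]
        s = dynamics.summarize_dynamics(values, (0.0, 20.0),
                                        {"a": (0.0, 10.0), "b": (10.0, 20.0)})
        assert s.per_session["a"].mean_rate == 1.0
        assert s.per_session["b"].mean_rate == 3.0

    def test_sigma_invariant_to_time_shift(self):
        rng = np.random.default_rng(6)
        spikes = np.sort(rng.uniform(0.0, 300.0, 900))
        a = dynamics.summarize_dynamics(
            dynamics.instantaneous_rates(spikes, (0.0, 300.0)), (0.0, 300.0))
        b = dynamics.summarize_dynamics(
            dynamics.instantaneous_rates(spikes + 1000.0, (1000.0, 1300.0)),
            (1000.0, 1300.0))
        assert a.sigma == pytest.approx(b.sigma)

    def test_poisson_sigma_matches_closed_form(self):
        """Homogeneous Poisson: SD of windowed rates = sqrt(rate/window)."""
        rng = np.random.default_rng(7)
        rate, window = 4.0, 3.0
        spikes = np.sort(rng.uniform(0.0, 1800.0, rng.poisson(rate * 1800)))
        series = dynamics.instantaneous_rates(spikes, (0.0, 1800.0))
        expected = np.sqrt(rate / window)
        assert dynamics.summarize_dynamics(series, (0.0, 1800.0)).sigma == \
            pytest.approx(expected, rel=0.1)


class TestNormalizedHistogram:
    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(8)
        h = dynamics.normalized_rate_histogram(rng.gamma(2, 1, 500))
        assert h.sum() == pytest.approx(1.0)

    def test_constant_series_masses_top_bin(self):
        h = dynamics.normalized_rate_histogram(np.full(50, 3.0))
        assert h[-1] == 1.0 and h[:-1].sum() == 0.0

    def test_hand_placed_values(self):
        h = dynamics.normalized_rate_histogram(np.array([0.0, 5.0, 10.0]))
        assert h[0] == pytest.approx(1 / 3)   # 0.0 -> [0, 0.1)
        assert h[5] == pytest.approx(1 / 3)   # 0.5 -> [0.5, 0.6)
        assert h[9] == pytest.approx(1 / 3)   # 1.0 -> top bin (right-closed)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dynamics.normalized_rate_histogram(np.zeros(10))


class TestSigmaMeanRegression:
    def test_exact_power_law_recovered(self):
        means = np.logspace(-0.5, 1.0, 20)
        fit = dynamics.fit_log_sigma_vs_mean(means, means)  # sigma = mean
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(9)
        means = rng.lognormal(0.5, 0.5, 40)
        sigmas = 0.6 * means ** 0.8 * rng.lognormal(0, 0.05, 40)
        fits, cmp = dynamics.sigma_vs_mean_regression(
            {"WT": (means, sigmas), "KO": (means, sigmas)})
        assert cmp.slope_diff == pytest.approx(0.0)
        assert cmp.p_slope == pytest.approx(1.0)
        assert cmp.p_intercept == pytest.approx(1.0)

    def test_scaled_sigma_lowers_intercept_not_slope(self):
        """KO-style sigma x0.7 at equal means: homogeneous slopes,
        significantly lower elevation."""
        rng = np.random.default_rng(10)
        means = rng.lognormal(0.5, 0.5, 120)
        noise = rng.lognormal(0, 0.08, 120)
        sigmas = 0.6 * means ** 0.8 * noise
        fits, cmp = dynamics.sigma_vs_mean_regression(
            {"WT": (means, sigmas), "KO": (means, 0.7 * sigmas)})
        assert cmp.p_slope > 0.05
        assert cmp.p_intercept < 0.05
        assert fits["KO"].intercept < fits["WT"].intercept

    def test_nonpositive_units_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            fit = dynamics.fit_log_sigma_vs_mean(
                np.array([1.0, 2.0, 3.0, 0.0]), np.array([1.0, 2.0, 3.0, 1.0]))
        assert fit.n == 3


class TestMaxDelta:
    def _iv(self, spikes_rate, start):
        return IntervalSet("z", "EE", [(start, start + 10.0)])

    def test_worked_example(self):
        # FR_I1=2, FR_I2=5, FR_C=3 over 10-s zones
        spikes = np.sort(np.r_[np.linspace(0, 9.99, 20),
                               np.linspace(20, 29.99, 50),
                               np.linspace(40, 49.99, 30)])
        md = dynamics.max_delta_fr(spikes, self._iv(2, 0.0), self._iv(5, 20.0),
                                   self._iv(3, 40.0))
        assert md.max_delta == pytest.approx(2.0)
        assert md.normalized_max_delta == pytest.approx(0.25)

    def test_equal_rates_give_zero(self):
        spikes = np.sort(np.r_[np.linspace(0, 9.99, 30),
                               np.linspace(20, 29.99, 30),
                               np.linspace(40, 49.99, 30)])
        md = dynamics.max_delta_fr(spikes, self._iv(3, 0.0), self._iv(3, 20.0),
                                   self._iv(3, 40.0))
        assert md.max_delta == 0.0 and md.normalized_max_delta == 0.0

    def test_silent_zone_saturates_normalized_delta(self):
        spikes = np.linspace(40, 49.99, 30)  # only the center zone fires
        md = dynamics.max_delta_fr(spikes, self._iv(0, 0.0), self._iv(0, 20.0),
                                   self._iv(3, 40.0))
        assert md.normalized_max_delta == pytest.approx(1.0)

    def test_normalized_delta_bounded(self):
        rng = np.random.default_rng(11)
        spikes = np.sort(rng.uniform(0.0, 60.0, 200))
        md = dynamics.max_delta_fr(spikes, self._iv(0, 0.0), self._iv(0, 20.0),
                                   self._iv(0, 40.0))
        assert 0.0 <= md.normalized_max_delta <= 1.0

    def test_zero_duration_zone_rejected(self):
        with pytest.raises(ValueError):
            dynamics.max_delta_fr([1.0], IntervalSet("z", "EE", []),
                                  self._iv(0, 20.0), self._iv(0, 40.0))
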