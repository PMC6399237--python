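"""Spike-train and tuning statistics against closed-form and brute-force
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from recipronet.stats import (
    ACFunction,
    TuningCurve,
    autocorrelation,
    cv,
    cv2,
    decorrelation_time,
    fano_factor,
    ff_from_cv_src,
    osi,
    population_autocorrelation,
    serial_rank_correlations,
    windowed_counts,
)


def _curve(rates, thetas=None):
    rates = np.asarray(rates, dtype=float)
    if thetas is None:
        thetas = np.arange(rates.size) * np.pi / rates.size
    return TuningCurve(np.asarray(thetas), rates)


class TestOSI:
    def test_flat_curve_is_untuned(self):
        assert osi(_curve([5.0] * 8)) == pytest.approx(0.0, abs=1e-12)

    def test_single_orientation_is_fully_selective(self):
        assert osi(_curve([1.0, 0.0, 0.0, 0.0])) == pytest.approx(1.0)

    def test_cosine_curve_closed_form(self):
        # r(theta) = r0 + r1 cos 2(theta - theta0) on an even grid -> r1/(2 r0)
        r0, r1, theta0 = 8.0, 3.0, 0.7
        th = np.arange(12) * np.pi / 12
        r = r0 + r1 * np.cos(2 * (th - theta0))
        # brute-force evaluation of the defining sum as the oracle
        z = np.sum(r * np.exp(2j * th))
        assert osi(_curve(r, th)) == pytest.approx(abs(z) / r.sum())
        assert osi(_curve(r, th)) == pytest.approx(r1 / (2 * r0), rel=1e-9)

    def test_invariances(self):
        rng = np.random.default_rng(0)
        th = np.arange(8) * np.pi / 8
        r = rng.uniform(0.5, 10.0, 8)
        base = osi(_curve(r, th))
        assert osi(_curve(3.7 * r, th)) == pytest.approx(base)
        shifted = np.mod(th + 0.4, np.pi)
        assert osi(_curve(r, shifted)) == pytest.approx(base)

    def test_all_zero_curve_signals_undefined(self):
        with pytest.raises(ValueError):
            osi(_curve([0.0] * 6))

    @given(st_h.lists(st_h.floats(0.01, 100.0), min_size=3, max_size=24))
    @settings(deadline=None, max_examples=50)
    def test_bounded_in_unit_interval(self, rates):
        val = osi(_curve(rates))
        assert -1e-12 <= val <= 1.0 + 1e-12


class TestFanoFactor:
    def test_deterministic_counts_have_zero_ff(self):
        assert fano_factor([7, 7, 7, 7]) == 0.0

    def test_two_trial_population_variance(self):
        # counts (1, 3): population variance 1, mean 2
        assert fano_factor([1, 3]) == pytest.approx(0.5)

    def test_poisson_counts_near_unity(self):
        rng = np.random.default_rng(42)
        counts = rng.poisson(5.0, 10_000)
        assert fano_factor(counts) == pytest.approx(
            1.0, abs=3 * np.sqrt(2 / 10_000)
        )

    def test_undefined_cases_raise(self):
        with pytest.raises(ValueError):
            fano_factor([5])
        with pytest.raises(ValueError):
            fano_factor([0, 0, 0])


class TestISIVariability:
    def test_regular_train_has_zero_cv_and_cv2(self):
        isis = np.full(50, 12.5)
        assert cv(isis) == 0.0
        assert cv2(isis) == 0.0

    def test_two_interval_arithmetic(self):
        assert cv([1.0, 3.0]) == pytest.approx(0.5)
        assert cv2([1.0, 3.0]) == pytest.approx(1.0)

    def test_exponential_isis_have_unit_cv(self):
        rng = np.random.default_rng(7)
        isis = rng.exponential(10.0, 100_000)
        assert cv(isis) == pytest.approx(1.0, abs=0.02)

    @given(st_h.lists(st_h.floats(0.1, 1e4), min_size=2, max_size=200))
    @settings(deadline=None, max_examples=50)
    def test_cv2_bounded(self, isis):
        assert 0.0 <= cv2(isis) <= 2.0

    def test_nonpositive_isis_rejected(self):
        with pytest.raises(ValueError):
            cv([1.0, 0.0])


class TestSerialRankCorrelations:
    def test_monotone_sequence_perfectly_correlated(self):
        isis = np.linspace(1, 50, 50)
        src = serial_rank_correlations(isis, max_order=3)
        assert src == pytest.approx([1.0, 1.0, 1.0])

    def test_alternating_sequence_anticorrelated(self):
        # ties within the short and long groups get average ranks, so the
        # rank sequence alternates between two values: perfect
        # anticorrelation at order 1, perfect correlation at order 2
        isis = np.tile([1.0, 10.0], 30)
        src = serial_rank_correlations(isis, max_order=2)
        assert src[0] == pytest.approx(-1.0)
        assert src[1] == pytest.approx(1.0)

    def test_shuffled_renewal_uncorrelated(self):
        rng = np.random.default_rng(3)
        isis = rng.exponential(5.0, 4000)
        src = serial_rank_correlations(isis, max_order=10)
        assert np.all(np.abs(src) < 3 / np.sqrt(4000))

    def test_renewal_identity(self):
        assert ff_from_cv_src(0.7, np.zeros(20)) == pytest.approx(0.49)

    def test_positive_correlations_raise_prediction(self):
        assert ff_from_cv_src(1.0, np.full(5, 0.1)) > 1.0
        assert ff_from_cv_src(1.0, np.full(5, -0.05)) < 1.0


class TestAutocorrelation:
    def test_poisson_ac_flat_at_squared_rate(self):
        rng = np.random.default_rng(11)
        rate = 30.0
        duration = 200_000.0
        t = np.sort(rng.uniform(0, duration,
                                rng.poisson(rate * duration * 1e-3)))
        ac = autocorrelation(t, duration, max_lag_ms=50)
        # disjoint-bin independence: every lag sits at rate^2
        assert ac.mean_rate_hz == pytest.approx(rate, rel=0.05)
        assert np.mean(ac.values) == pytest.approx(rate**2, rel=0.05)
        assert np.std(ac.values) < 0.3 * rate**2

    def test_periodic_train_peaks_at_multiples_of_period(self):
        period = 20.0
        t = np.arange(0, 10_000.0, period)
        ac = autocorrelation(t, 10_000.0, max_lag_ms=100)
        peaks = ac.lags_ms[ac.values > 0.5 * ac.values.max()]
        assert np.all(peaks % period == 0)

    def test_population_average_is_mean_of_neuron_acs(self):
        rng = np.random.default_rng(5)
        duration = 20_000.0
        trains = [
            np.sort(rng.uniform(0, duration, 300)) for _ in range(4)
        ]
        pop = population_autocorrelation(trains, duration, max_lag_ms=20)
        per = np.mean(
            [autocorrelation(t, duration, 20).values for t in trains], axis=0
        )
        assert pop.values == pytest.approx(per)

    def test_rate_normalized_view(self):
        t = np.arange(0, 5000.0, 10.0)
        ac = autocorrelation(t, 5000.0, 50).as_rate_normalized()
        assert ac.normalization == "rate"


class TestDecorrelationTime:
    def test_recovers_planted_exponential_decay(self):
        # noiseless synthetic AC(tau) = r^2 + A exp(-tau/tau0)
        tau0, r, amp = 17.0, 10.0, 40.0
        lags = np.arange(1.0, 201.0)
        ac = ACFunction(lags, r**2 + amp * np.exp(-lags / tau0), r)
        fit = decorrelation_time(ac)
        assert fit.tau_ms == pytest.approx(tau0, rel=0.05)

    def test_flat_ac_signals_undefined(self):
        lags = np.arange(1.0, 101.0)
        ac = ACFunction(lags, np.full(100, 25.0), 5.0)
        with pytest.raises(ValueError):
            decorrelation_time(ac)

    def test_loglog_variant_reports_power_slope(self):
        lags = np.arange(1.0, 201.0)
        r = 5.0
        ac = ACFunction(lags, r**2 + 50.0 * lags**-1.5, r)
        fit = decorrelation_time(ac, loglog=True)
        assert fit.tau_ms == pytest.approx(1.5, rel=0.05)


class TestWindowedCounts:
    def test_counts_partition_the_train(self):
        t = np.arange(0.5, 1000.0, 1.0)
        counts = windowed_counts(t, 1000.0, 100.0)
        assert counts.sum() == len(t)
        assert counts.shape == (10,)
        assert np.all(counts == 100)
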