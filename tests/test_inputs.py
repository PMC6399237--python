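"""Synaptic filtering, background drive, feedforward tuning and the colored
noise process."""

import numpy as np
import pytest

from recipronet.inputs import (
    BackgroundParams,
    FeedforwardParams,
    OUProcess,
    SynapseParams,
    background_conductance,
    draw_disorder,
    feedforward_rate,
    mixed_driving_force,
    recurrent_current,
    synapse_decay_and_jump,
)


class TestExponentialSynapse:
    def test_pure_decay_between_spikes(self):
        g = 1.0
        tau = 3.0
        for _ in range(10):
            g = synapse_decay_and_jump(g, 0.5, 0, 0.2, tau)
        assert g == pytest.approx(np.exp(-5.0 / tau))

    def test_single_transient_has_unit_integral_times_gbar(self):
        # integral of (gbar/tau) e^{-t/tau} is gbar
        gbar, tau, dt = 0.4, 3.0, 0.01
        g = synapse_decay_and_jump(0.0, dt, 1, gbar, tau)
        total = 0.0
        for _ in range(int(100 * tau / dt)):
            total += g * dt
            g = synapse_decay_and_jump(g, dt, 0, gbar, tau)
        assert total == pytest.approx(gbar, rel=1e-2)

    def test_poisson_drive_stationary_mean(self):
        # K inputs at rate r: mean conductance gbar K r (rate in 1/ms)
        rng = np.random.default_rng(0)
        gbar, tau, dt, k, r_hz = 0.3, 3.0, 0.1, 100, 20.0
        r_ms = r_hz * 1e-3
        g, acc, n = 0.0, 0.0, 80_000
        for i in range(n):
            g = synapse_decay_and_jump(g, dt, rng.poisson(k * r_ms * dt),
                                       gbar, tau)
            if i > n // 10:
                acc += g
        assert acc / (0.9 * n) == pytest.approx(gbar * k * r_ms, rel=0.05)


class TestDrivingForceMixture:
    def test_rho_limits(self):
        v, v_rev, v_l = -55.0, 0.0, -65.0
        assert mixed_driving_force(v, v_rev, v_l, 1.0) == v - v_rev
        assert mixed_driving_force(v, v_rev, v_l, 0.0) == v_l - v_rev

    def test_at_reversal_only_current_term_remains(self):
        syn = SynapseParams(rho=0.4)
        i = recurrent_current(syn.v_e, 2.0, 0.0, syn, v_l=-65.0)
        assert i == pytest.approx(-2.0 * 0.6 * (-65.0 - syn.v_e))


class TestBackgroundDrive:
    def test_zero_rate_is_silent(self):
        p = BackgroundParams(rate=0.0)
        assert background_conductance(p, 100, 1.5) == 0.0

    def test_zero_noise_is_constant_mean(self):
        p = BackgroundParams(g_b=0.3, rate=5.0, noise=0.0)
        k = 100
        expected = 0.3 / np.sqrt(k) * k * 5e-3
        assert background_conductance(p, k, 2.7) == pytest.approx(expected)

    def test_negative_excursions_clipped(self):
        p = BackgroundParams(g_b=0.3, rate=5.0, noise=1.0)
        assert background_conductance(p, 100, -1e4) == 0.0


class TestFeedforwardTuning:
    def test_contrast_response_amplitude(self):
        # R1(C) = R1 log10(C+1): 20 Hz at C = 100 gives ~40.09 Hz
        ff = FeedforwardParams(r1=20.0)
        assert ff.amplitude(100.0) == pytest.approx(20 * np.log10(101.0))
        assert ff.amplitude(0.0) == 0.0

    def test_zero_contrast_removes_orientation_dependence(self):
        rng = np.random.default_rng(1)
        dis = draw_disorder(200, rng)
        ff = FeedforwardParams(k_ff=100)
        r1 = feedforward_rate(0.2, dis, ff, 500, contrast=0.0)
        r2 = feedforward_rate(1.9, dis, ff, 500, contrast=0.0)
        assert np.allclose(r1, r2)

    def test_rate_maximal_at_preferred_orientation(self):
        rng = np.random.default_rng(2)
        dis = draw_disorder(50, rng)
        ff = FeedforwardParams(k_ff=100)
        i = 7
        at_pref = feedforward_rate(dis.delta[i], dis, ff, 500, 100.0)[i]
        for theta in np.linspace(0, np.pi, 13)[:-1]:
            assert feedforward_rate(theta, dis, ff, 500, 100.0)[i] \
                <= at_pref + 1e-9
        assert np.all(feedforward_rate(0.5, dis, ff, 500, 100.0) >= 0)

    def test_scaling_with_in_degree(self):
        # gbar_ff = G_ff/(c_ff sqrt(K)); mean drive grows as sqrt(K)
        ff = FeedforwardParams(g_ff=0.03, k_ff=100)
        assert ff.scaled(500) * ff.c_ff(500) * 500 == pytest.approx(
            0.03 * np.sqrt(500))


class TestOUNoise:
    def test_stationary_moments_and_autocorrelation(self):
        tau, dt, n = 3.0, 0.5, 400_000
        ou = OUProcess(1, tau, np.random.default_rng(3))
        xs = np.empty(n)
        for i in range(n):
            xs[i] = ou.step(dt)[0]
        var = 1.0 / (2.0 * tau)
        assert xs.mean() == pytest.approx(0.0, abs=4 * np.sqrt(var / n) * 10)
        assert xs.var() == pytest.approx(var, rel=0.05)
        lag = 4  # 2 ms
        emp = np.mean(xs[:-lag] * xs[lag:])
        assert emp == pytest.approx(var * np.exp(-lag * dt / tau), rel=0.1)

    def test_disorder_draws_have_declared_laws(self):
        rng = np.random.default_rng(4)
        dis = draw_disorder(200_000, rng)
        assert dis.x.mean() == pytest.approx(0.0, abs=0.01)
        assert dis.x.std() == pytest.approx(1.0, rel=0.01)
        # Rayleigh with density z exp(-z^2/2): mean sqrt(pi/2)
        assert dis.z1.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=0.01)
        assert dis.delta.min() >= 0 and dis.delta.max() < np.pi
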