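"""Synaptic, background and feedforward inputs.

All synaptic interactions are conductance/current mixtures: a presynaptic
conductance g multiplies a driving force that interpolates between the true
conductance-based form (V - V_rev) and a current-based form (V_L - V_rev)
with mixing fraction rho,

    I = -g [rho (V - V_rev) + (1 - rho) (V_L - V_rev)].

Recurrent conductances are exponentially filtered spike trains with time
constant tau_syn; each presynaptic spike adds gbar/tau_syn so that the time
integral of one postsynaptic transient equals gbar.  Synaptic strengths are
scaled with the mean in-degree K as gbar_AB = G_AB / sqrt(K), the strong-
coupling scaling under which the network settles into the balanced state.

The background drive stands in for the rest of cortex: a mean conductance
gbar_b K R_b plus Gaussian fluctuations of relative size 1/sqrt(K), colored
by an Ornstein–Uhlenbeck process with correlation time tau_syn.

The feedforward drive is a reduction of orientation-selective layer-4 input:
on average c_ff K presynaptic L4 cells firing at baseline R_0 plus a
contrast-dependent amplitude R_1(C) = R_1 log10(C + 1).  Because the
presynaptic pool is finite, each neuron keeps a quenched O(sqrt(c_ff K))
sample fluctuation with an untuned part (standard normal x_i) and a tuned
part z_1,i cos 2(theta - Delta_i) with Rayleigh amplitude and uniformly
distributed preferred orientation Delta_i — the salt-and-pepper arrangement
of rodent V1.  The rate is shot-noise filtered through the same exponential
synapse, with sqrt(R) noise for the finite-rate Poisson fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseParams",
    "BackgroundParams",
    "FeedforwardParams",
    "QuenchedDisorder",
    "draw_disorder",
    "synapse_decay_and_jump",
    "recurrent_current",
    "mixed_driving_force",
    "background_conductance",
    "feedforward_rate",
    "feedforward_conductance",
    "OUProcess",
]


@dataclass(frozen=True)
class SynapseParams:
    """Recurrent coupling strengths and the shared synaptic kinetics.

    ``g_ee`` etc. are the unscaled couplings G_AB (ms * mS/cm^2); the
    strength actually used per synapse is ``G_AB / sqrt(K)``.  ``rho`` mixes
    conductance- and current-based driving forces; ``v_e``/``v_i`` are the
    excitatory and inhibitory reversal potentials (mV).
    """

    g_ee: float = 0.15
    g_ie: float = 0.45
    g_ei: float = 2.0
    g_ii: float = 3.0
    tau_syn: float = 3.0
    rho: float = 0.5
    v_e: float = 0.0
    v_i: float = -80.0

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")

    def scaled(self, block: str, k: int) -> float:
        """gbar_AB = G_AB / sqrt(K) for block in {EE, IE, EI, II}."""
        g = {"EE": self.g_ee, "IE": self.g_ie,
             "EI": self.g_ei, "II": self.g_ii}[block]
        return g / np.sqrt(k)


@dataclass(frozen=True)
class BackgroundParams:
    """Unstructured drive from outside the modeled circuit.

    ``g_b`` is the unscaled background coupling (scaled as G_b / sqrt(K));
    ``rate`` is the effective presynaptic rate R_b in Hz.  Setting
    ``noise`` to 0 freezes the drive at its mean gbar_b K R_b.
    """

    g_b: float = 0.3
    rate: float = 5.0
    noise: float = 3.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("background rate must be nonnegative")


@dataclass(frozen=True)
class FeedforwardParams:
    """Orientation-tuned layer-4 drive for one population.

    ``g_ff`` is the unscaled strength G_ff (scaled as G_ff / (c_ff sqrt(K)));
    ``k_ff`` the mean number of L4 inputs; ``r0``/``r1`` the L4 baseline and
    response amplitude in Hz; ``tuning_strength`` the L4 tuning factor
    xi_A; ``noise`` scales the sqrt(R) shot noise (0 disables it).
    """

    g_ff: float = 0.028
    k_ff: int = 100
    r0: float = 2.0
    r1: float = 20.0
    tuning_strength: float = 0.8
    noise: float = 1.0

    def c_ff(self, k: int) -> float:
        return self.k_ff / k

    def scaled(self, k: int) -> float:
        """gbar_ff = G_ff / (c_ff sqrt(K))."""
        return self.g_ff / (self.c_ff(k) * np.sqrt(k))

    def amplitude(self, contrast: float) -> float:
        """Contrast response R_1(C) = R_1 * log10(C + 1), in Hz."""
        if contrast < 0:
            raise ValueError("contrast must be nonnegative")
        return self.r1 * np.log10(contrast + 1.0)


@dataclass(frozen=True)
class QuenchedDisorder:
    """Per-neuron frozen randomness of the feedforward pool for one
    population: untuned sample fluctuation ``x`` (standard normal), tuned
    amplitude ``z1`` (Rayleigh, density z exp(-z^2/2)) and preferred
    orientation ``delta`` (uniform on [0, pi))."""

    x: np.ndarray
    z1: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.z1 < 0):
            raise ValueError("Rayleigh amplitudes must be nonnegative")
        if np.any((self.delta < 0) | (self.delta >= np.pi)):
            raise ValueError("preferred orientations must lie in [0, pi)")


def draw_disorder(n: int, rng: np.random.Generator) -> QuenchedDisorder:
    """Draw one frozen disorder realization for ``n`` neurons."""
    return QuenchedDisorder(
        x=rng.standard_normal(n),
        z1=rng.rayleigh(scale=1.0, size=n),
        delta=rng.uniform(0.0, np.pi, size=n),
    )


def synapse_decay_and_jump(g, dt, n_spikes, gbar, tau_syn):
    """One step of the exponential synapse: decay by exp(-dt/tau) then add
    gbar/tau per presynaptic spike arriving in the step."""
    return g * np.exp(-dt / tau_syn) + (gbar / tau_syn) * n_spikes


def mixed_driving_force(v, v_rev, v_l, rho):
    """rho (V - V_rev) + (1 - rho)(V_L - V_rev)."""
    return rho * (np.asarray(v) - v_rev) + (1.0 - rho) * (v_l - v_rev)


def recurrent_current(v, g_exc, g_inh, params: SynapseParams, v_l: float):
    """Total recurrent synaptic current density for conductances ``g_exc``
    (from excitatory partners) and ``g_inh`` (from inhibitory partners)."""
    return -(
        g_exc * mixed_driving_force(v, params.v_e, v_l, params.rho)
        + g_inh * mixed_driving_force(v, params.v_i, v_l, params.rho)
    )


def background_conductance(params: BackgroundParams, k: int, eta):
    """Instantaneous background conductance gbar_b K (R_b + sqrt(R_b/K) eta),
    clipped at zero.  Rates are converted to 1/ms so the product with the
    O(1/sqrt(K)) coupling is a conductance in mS/cm^2."""
    gbar = params.g_b / np.sqrt(k)
    r = params.rate * 1e-3
    val = gbar * k * (r + params.noise * np.sqrt(r / k) * np.asarray(eta))
    return np.clip(val, 0.0, None)


def feedforward_rate(
    theta: float,
    disorder: QuenchedDisorder,
    params: FeedforwardParams,
    k: int,
    contrast: float,
) -> np.ndarray:
    """Summed L4 input rate per neuron (Hz) at stimulus orientation
    ``theta``: untuned mean c_ff K [R0 + R1(C)] plus the quenched
    O(sqrt(c_ff K)) fluctuation with tuned component
    xi z1 cos 2(theta - Delta); negative values are clipped to zero."""
    if not 0.0 <= theta < np.pi:
        raise ValueError("theta must lie in [0, pi)")
    ck = params.c_ff(k) * k
    r1c = params.amplitude(contrast)
    tuned = params.tuning_strength * disorder.z1 * np.cos(
        2.0 * (theta - disorder.delta)
    )
    r = ck * (params.r0 + r1c) + np.sqrt(ck) * (
        disorder.x + r1c * (disorder.x + tuned)
    )
    return np.clip(r, 0.0, None)


def feedforward_conductance(g, r_tot_hz, eta, params: FeedforwardParams,
                            k: int, dt: float, tau_syn: float):
    """One exact-discretization step of the feedforward synapse
    tau dg/dt = -g + gbar_ff (R + sqrt(R) eta), rates in 1/ms."""
    gbar = params.scaled(k)
    r = np.asarray(r_tot_hz) * 1e-3
    drive = np.clip(r + params.noise * np.sqrt(r) * np.asarray(eta), 0.0, None)
    decay = np.exp(-dt / tau_syn)
    return g * decay + (1.0 - decay) * gbar * drive


class OUProcess:
    """Ornstein–Uhlenbeck noise with correlation time ``tau`` and stationary
    autocovariance exp(-|dt|/tau) / (2 tau): the unit-spectral-density
    exponential kernel, so that sqrt(rate) * eta models Poisson shot noise
    after synaptic filtering.  Uses the exact discretization, which preserves
    the stationary law for any step size."""

    def __init__(self, n: int, tau: float, rng: np.random.Generator):
        if tau <= 0:
            raise ValueError("correlation time must be positive")
        self.tau = tau
        self.sigma = np.sqrt(1.0 / (2.0 * tau))
        self.rng = rng
        self.state = self.sigma * rng.standard_normal(n)

    def step(self, dt: float) -> np.ndarray:
        a = np.exp(-dt / self.tau)
        self.state = a * self.state + self.sigma * np.sqrt(
            1.0 - a * a
        ) * self.rng.standard_normal(self.state.size)
        return self.state
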