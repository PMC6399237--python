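"""Time-stepped simulation of the two-population balanced network.

The integrator advances all neurons on a fixed grid (default dt = 0.05 ms)
with the exponential-Euler scheme: at frozen gating the membrane equation is
linear in V, so V relaxes exactly toward the conductance-weighted reversal
potential (and can never overshoot it); the gating variables likewise relax
exponentially toward voltage-dependent steady states that are pre-tabulated
on a fine voltage grid from the pluggable kinetics table.
Synaptic conductances decay exponentially between spikes and jump by
gbar/tau_syn per presynaptic spike, delivered along a compressed out-edge
list built from the connectivity blocks.  Background and feedforward drives
are colored by per-neuron Ornstein–Uhlenbeck noise with the synaptic
correlation time.  The inner loop is compiled with numba.

Spikes are detected as upward crossings of -20 mV with a 2 ms lockout on
detection (the dynamics are never reset), and timed by linear interpolation
within the step.

Reproducibility: a single root seed spawns independent child streams for
connectivity (per block), quenched disorder and per-trial noise/initial
conditions, so that sweeping the reciprocity of one connection class leaves
every other random ingredient bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .inputs import (
    BackgroundParams,
    FeedforwardParams,
    QuenchedDisorder,
    SynapseParams,
    draw_disorder,
    feedforward_rate,
)
from .neuron import (
    E_CELL,
    I_CELL,
    KineticsTable,
    NeuronParams,
    WANG_BUZSAKI,
    steady_state_gating,
    z_inf,
)
from .topology import ConnectivityMatrix, TopologyConfig, generate_connectivity

__all__ = [
    "RunConfig",
    "SpikeData",
    "run_trial",
    "run_tuning_experiment",
    "run_fano_experiment",
    "run_reciprocity_sweep",
]

SPIKE_THRESHOLD = -20.0  # mV, upward crossing
REFRACTORY_MS = 2.0      # lockout on detection only

_V_MIN, _V_MAX, _V_STEP = -120.0, 60.0, 0.05


@dataclass(frozen=True)
class SpikeData:
    """Spike times of one trial: a list of strictly increasing per-neuron
    arrays (ms, within [0, duration]), with excitatory neurons first."""

    trains: list
    n_e: int
    duration_ms: float
    theta: float
    seed: int

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def population(self, which: str) -> list:
        if which == "E":
            return self.trains[: self.n_e]
        if which == "I":
            return self.trains[self.n_e:]
        raise ValueError("population must be 'E' or 'I'")

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.trains])

    def rates_hz(self) -> np.ndarray:
        return self.counts() / (self.duration_ms * 1e-3)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    topology: TopologyConfig
    neuron_e: NeuronParams = E_CELL
    neuron_i: NeuronParams = I_CELL
    synapse: SynapseParams = SynapseParams()
    background_e: BackgroundParams = BackgroundParams()
    background_i: BackgroundParams = BackgroundParams()
    feedforward_e: FeedforwardParams = FeedforwardParams(g_ff=0.028, k_ff=100)
    feedforward_i: FeedforwardParams = FeedforwardParams(g_ff=0.038, k_ff=800)
    dt: float = 0.05
    t_transient: float = 1000.0
    t_measure: float = 10_000.0
    orientations: tuple = tuple(np.arange(12) * np.pi / 12)
    contrast: float = 100.0
    n_trials: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_measure <= 0 or self.t_transient < 0:
            raise ValueError("dt and durations must be positive")
        if any(not 0 <= th < np.pi for th in self.orientations):
            raise ValueError("orientations must lie in [0, pi)")

    @classmethod
    def desk_scale(cls, n: int = 2000, k: int = 100, seed: int = 0,
                   **overrides) -> "RunConfig":
        """Reduced-scale profile: N_E = N_I = ``n`` neurons per population
        and mean in-degree ``k``, with the K-scaled couplings unchanged.
        The feedforward in-degrees keep their ratio to K (1:5 for E, 8:1
        relative to the full-scale 100:800 at K = 500)."""
        kff_e = max(int(round(k * 0.2)), 1)
        kff_i = max(int(round(k * 1.6)), 1)
        topo = TopologyConfig(n_e=n, n_i=n, k=k, seed=seed)
        cfg = cls(
            topology=topo,
            feedforward_e=FeedforwardParams(g_ff=0.028, k_ff=kff_e),
            feedforward_i=FeedforwardParams(g_ff=0.038, k_ff=kff_i),
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def full_scale(cls, n: int = 10_000, seed: int = 0,
                    **overrides) -> "RunConfig":
        """Full-scale profile: K = 500, feedforward in-degrees 100 (E) and
        800 (I)."""
        topo = TopologyConfig(n_e=n, n_i=n, k=500, seed=seed)
        cfg = cls(
            topology=topo,
            feedforward_e=FeedforwardParams(g_ff=0.028, k_ff=100),
            feedforward_i=FeedforwardParams(g_ff=0.038, k_ff=800),
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg

    def with_reciprocity(self, which: str, p: float) -> "RunConfig":
        """Copy with the reciprocity of one connection class changed; all
        seeds and every other parameter are untouched."""
        key = {"EE": "p_ee", "II": "p_ii", "EI": "p_ei"}[which]
        return replace(self, topology=replace(self.topology, **{key: p}))


# ---------------------------------------------------------------------------
# seed plumbing

def _seed_streams(config: RunConfig):
    """Child seed sequences: (disorder_E, disorder_I, trial noise root)."""
    ss = np.random.SeedSequence(config.seed)
    return ss.spawn(3)


def network_disorder(config: RunConfig) -> tuple[QuenchedDisorder, QuenchedDisorder]:
    """Quenched feedforward disorder for both populations; depends only on
    the root seed and population sizes, never on reciprocity."""
    s_e, s_i, _ = _seed_streams(config)
    return (
        draw_disorder(config.topology.n_e, np.random.default_rng(s_e)),
        draw_disorder(config.topology.n_i, np.random.default_rng(s_i)),
    )


def _trial_seed(config: RunConfig, trial: int) -> int:
    """31-bit kernel seed for one trial's noise and initial conditions."""
    _, _, s_trials = _seed_streams(config)
    child = np.random.SeedSequence(
        entropy=s_trials.entropy, spawn_key=s_trials.spawn_key + (trial,)
    )
    return int(child.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# kernel inputs

def _gating_tables(kinetics: KineticsTable, dt: float):
    """Pre-tabulated m_inf^3, steady states and per-step exponential decay
    factors of h and n (with the phi factor) and z_inf on the voltage grid."""
    v = np.arange(_V_MIN, _V_MAX + _V_STEP, _V_STEP)
    ah, bh = kinetics.alpha_h(v), kinetics.beta_h(v)
    an, bn = kinetics.alpha_n(v), kinetics.beta_n(v)
    am, bm = kinetics.alpha_m(v), kinetics.beta_m(v)
    phi = kinetics.phi
    return (
        (am / (am + bm)) ** 3,
        ah / (ah + bh), np.exp(-phi * (ah + bh) * dt),
        an / (an + bn), np.exp(-phi * (an + bn) * dt),
        z_inf(v),
    )


def _build_out_edges(conn: ConnectivityMatrix, syn: SynapseParams, k: int):
    """Compressed out-edge list over global neuron ids (E first), with the
    per-spike conductance increments gbar_AB / tau_syn as weights."""
    n_e, n_i = conn.n_e, conn.n_i
    csc = {name: conn.blocks[name].tocsc() for name in conn.blocks}
    w = {name: syn.scaled(name, k) / syn.tau_syn
         for name in ("EE", "IE", "EI", "II")}
    indptr = np.zeros(n_e + n_i + 1, dtype=np.int64)
    targets_parts, weights_parts = [], []
    for j in range(n_e):
        t_e = csc["EE"].indices[csc["EE"].indptr[j]:csc["EE"].indptr[j + 1]]
        t_i = csc["IE"].indices[csc["IE"].indptr[j]:csc["IE"].indptr[j + 1]]
        targets_parts.append(t_e)
        targets_parts.append(t_i + n_e)
        weights_parts.append(np.full(t_e.size, w["EE"]))
        weights_parts.append(np.full(t_i.size, w["IE"]))
        indptr[j + 1] = indptr[j] + t_e.size + t_i.size
    for j in range(n_i):
        t_e = csc["EI"].indices[csc["EI"].indptr[j]:csc["EI"].indptr[j + 1]]
        t_i = csc["II"].indices[csc["II"].indptr[j]:csc["II"].indptr[j + 1]]
        targets_parts.append(t_e)
        targets_parts.append(t_i + n_e)
        weights_parts.append(np.full(t_e.size, w["EI"]))
        weights_parts.append(np.full(t_i.size, w["II"]))
        gj = n_e + j
        indptr[gj + 1] = indptr[gj] + t_e.size + t_i.size
    targets = np.concatenate(targets_parts).astype(np.int64)
    weights = np.concatenate(weights_parts)
    return indptr, targets, weights


@njit(cache=True)
def _run_kernel(
    n_e, n_total, dt, n_steps, record_start_step,
    # per-neuron biophysics
    c_m, g_l, v_l, g_na, v_na, g_k, v_k, g_adapt, z_decay,
    # gating tables on the voltage grid
    v_min, v_step, m_inf3_t, h_inf_t, h_dec_t, n_inf_t, n_dec_t, z_inf_t,
    # synapse
    syn_decay, ff_decay, rho, v_e_rev, v_i_rev,
    # background (per neuron): mean and noise amplitude of the conductance
    gb_mean, gb_amp,
    # feedforward (per neuron): rate (1/ms), gbar, sqrt-rate noise scale
    r_ff, gbar_ff, ff_noise,
    # OU noise
    ou_a, ou_s,
    # state (modified in place)
    v, h, n_gate, z, g_exc, g_inh, g_ff, eta_b, eta_ff,
    # connectivity out-edges
    out_indptr, out_targets, out_weights,
    seed,
    spike_times, spike_ids,
):
    """Inner loop; returns (number of recorded spikes, error code).

    Error codes: 0 ok, 1 non-finite membrane potential, 2 spike buffer full.
    """
    np.random.seed(seed)
    last_spike = np.full(n_total, -1e9)
    n_spikes = 0
    cap = spike_times.size
    n_table = m_inf3_t.size
    for step in range(n_steps):
        t_now = step * dt
        for i in range(n_total):
            # colored noise for background and feedforward drives
            eta_b[i] = ou_a * eta_b[i] + ou_s * np.random.standard_normal()
            eta_ff[i] = ou_a * eta_ff[i] + ou_s * np.random.standard_normal()
            g_b = gb_mean[i] + gb_amp[i] * eta_b[i]
            if g_b < 0.0:
                g_b = 0.0
            r = r_ff[i]
            drive = r + ff_noise[i] * np.sqrt(r) * eta_ff[i]
            if drive < 0.0:
                drive = 0.0
            g_ff[i] = g_ff[i] * ff_decay + (1.0 - ff_decay) * gbar_ff[i] * drive

            vi = v[i]
            # table lookup with linear interpolation
            pos = (vi - v_min) / v_step
            if pos < 0.0:
                pos = 0.0
            elif pos > n_table - 1.001:
                pos = n_table - 1.001
            idx = int(pos)
            frac = pos - idx
            m3 = m_inf3_t[idx] + frac * (m_inf3_t[idx + 1] - m_inf3_t[idx])
            h_inf = h_inf_t[idx] + frac * (h_inf_t[idx + 1] - h_inf_t[idx])
            h_dec = h_dec_t[idx] + frac * (h_dec_t[idx + 1] - h_dec_t[idx])
            ninf = n_inf_t[idx] + frac * (n_inf_t[idx + 1] - n_inf_t[idx])
            n_dec = n_dec_t[idx] + frac * (n_dec_t[idx + 1] - n_dec_t[idx])
            zinf = z_inf_t[idx] + frac * (z_inf_t[idx + 1] - z_inf_t[idx])

            # exponential-Euler voltage update: the membrane equation is
            # linear in V at frozen gating, V relaxes toward the
            # conductance-weighted reversal potential
            gx = g_exc[i] + g_ff[i] + g_b
            gna = g_na[i] * m3 * h[i]
            gk = g_k[i] * n_gate[i] ** 4
            gad = g_adapt[i] * z[i]
            g_tot = g_l[i] + gna + gk + gad + rho * (gx + g_inh[i])
            b = (g_l[i] * v_l[i] + gna * v_na[i] + (gk + gad) * v_k[i]
                 + rho * (gx * v_e_rev + g_inh[i] * v_i_rev)
                 - (1.0 - rho) * (gx * (v_l[i] - v_e_rev)
                                  + g_inh[i] * (v_l[i] - v_i_rev)))
            v_infty = b / g_tot
            v_new = v_infty + (vi - v_infty) * np.exp(-g_tot * dt / c_m[i])
            h[i] = h_inf + (h[i] - h_inf) * h_dec
            n_gate[i] = ninf + (n_gate[i] - ninf) * n_dec
            z[i] = zinf + (z[i] - zinf) * z_decay[i]

            if vi < SPIKE_THRESHOLD <= v_new and \
                    t_now - last_spike[i] > REFRACTORY_MS:
                t_sp = t_now + dt * (SPIKE_THRESHOLD - vi) / (v_new - vi)
                last_spike[i] = t_sp
                if step >= record_start_step:
                    if n_spikes >= cap:
                        return n_spikes, 2
                    spike_times[n_spikes] = t_sp
                    spike_ids[n_spikes] = i
                    n_spikes += 1
                # deliver to postsynaptic targets
                for e in range(out_indptr[i], out_indptr[i + 1]):
                    tgt = out_targets[e]
                    if i < n_e:
                        g_exc[tgt] += out_weights[e]
                    else:
                        g_inh[tgt] += out_weights[e]
            v[i] = v_new
        for i in range(n_total):
            g_exc[i] *= syn_decay
            g_inh[i] *= syn_decay
        if not np.isfinite(v[0]) or not np.isfinite(v[n_total - 1]):
            return n_spikes, 1
    return n_spikes, 0


def run_trial(
    config: RunConfig,
    connectivity: ConnectivityMatrix | None = None,
    disorder: tuple[QuenchedDisorder, QuenchedDisorder] | None = None,
    theta: float = 0.0,
    trial: int = 0,
    kinetics: KineticsTable = WANG_BUZSAKI,
    max_rate_hz: float = 200.0,
) -> SpikeData:
    """Simulate one trial and return the spikes recorded after the
    transient, with times relative to the start of the measurement window.

    ``connectivity`` and ``disorder`` may be passed in to amortize their
    construction over trials; when omitted they are generated from the
    config seeds.  ``trial`` indexes the per-trial noise/initial-condition
    stream; identical arguments give bit-identical output.
    """
    topo = config.topology
    if connectivity is None:
        connectivity = generate_connectivity(topo)
    if disorder is None:
        disorder = network_disorder(config)
    dis_e, dis_i = disorder
    n_e, n_i = topo.n_e, topo.n_i
    n_total = n_e + n_i
    k = topo.k
    syn = config.synapse
    dt = config.dt

    def per_neuron(attr):
        pe = getattr(config.neuron_e, attr)
        pi = getattr(config.neuron_i, attr)
        return np.concatenate([np.full(n_e, pe), np.full(n_i, pi)])

    c_m, g_l, v_l = per_neuron("c_m"), per_neuron("g_l"), per_neuron("v_l")
    g_na, v_na = per_neuron("g_na"), per_neuron("v_na")
    g_k, v_k = per_neuron("g_k"), per_neuron("v_k")
    g_adapt = per_neuron("g_adapt")
    z_decay = np.exp(-dt / per_neuron("tau_adapt"))

    tables = _gating_tables(kinetics, dt)
    m3_t, h_inf_t, h_dec_t, n_inf_t, n_dec_t, z_inf_t = tables

    # background: mean gbar_b K R and O(sqrt(K)) noise amplitude, rates in 1/ms
    gb_mean = np.empty(n_total)
    gb_amp = np.empty(n_total)
    for sl, bg in ((slice(0, n_e), config.background_e),
                   (slice(n_e, n_total), config.background_i)):
        gbar = bg.g_b / np.sqrt(k)
        r_ms = bg.rate * 1e-3
        gb_mean[sl] = gbar * k * r_ms
        gb_amp[sl] = bg.noise * gbar * k * np.sqrt(r_ms / k)

    # feedforward: per-neuron quenched rate at this orientation
    r_ff = np.concatenate([
        feedforward_rate(theta, dis_e, config.feedforward_e, k,
                         config.contrast),
        feedforward_rate(theta, dis_i, config.feedforward_i, k,
                         config.contrast),
    ]) * 1e-3
    gbar_ff = np.concatenate([
        np.full(n_e, config.feedforward_e.scaled(k)),
        np.full(n_i, config.feedforward_i.scaled(k)),
    ])
    ff_noise = np.concatenate([
        np.full(n_e, config.feedforward_e.noise),
        np.full(n_i, config.feedforward_i.noise),
    ])

    ou_a = np.exp(-dt / syn.tau_syn)
    ou_sigma = np.sqrt(1.0 / (2.0 * syn.tau_syn))
    ou_s = ou_sigma * np.sqrt(1.0 - ou_a**2)

    out_indptr, out_targets, out_weights = _build_out_edges(
        connectivity, syn, k
    )

    # per-trial initial conditions: V uniform in [V_L, V_L + 10 mV], gating
    # at steady state for that voltage, OU states at stationarity
    rng = np.random.default_rng(_trial_seed(config, trial))
    v0 = v_l + 10.0 * rng.random(n_total)
    h0, n0, z0 = steady_state_gating(v0, kinetics)
    z0 = np.where(g_adapt > 0, z0, 0.0)
    eta_b0 = ou_sigma * rng.standard_normal(n_total)
    eta_ff0 = ou_sigma * rng.standard_normal(n_total)
    g_exc0 = np.zeros(n_total)
    g_inh0 = np.zeros(n_total)
    g_ff0 = gbar_ff * r_ff  # stationary mean of the filtered drive
    kernel_seed = int(rng.integers(2**31 - 1))

    duration = config.t_transient + config.t_measure
    n_steps = int(round(duration / dt))
    record_start = int(round(config.t_transient / dt))
    cap = int(n_total * config.t_measure * 1e-3 * max_rate_hz) + 1000
    spike_times = np.empty(cap)
    spike_ids = np.empty(cap, dtype=np.int64)

    n_spikes, err = _run_kernel(
        n_e, n_total, dt, n_steps, record_start,
        c_m, g_l, v_l, g_na, v_na, g_k, v_k, g_adapt, z_decay,
        _V_MIN, _V_STEP, m3_t, h_inf_t, h_dec_t, n_inf_t, n_dec_t, z_inf_t,
        np.exp(-dt / syn.tau_syn), np.exp(-dt / syn.tau_syn),
        syn.rho, syn.v_e, syn.v_i,
        gb_mean, gb_amp, r_ff, gbar_ff, ff_noise,
        ou_a, ou_s,
        v0.astype(float), np.asarray(h0, float), np.asarray(n0, float),
        np.asarray(z0, float), g_exc0, g_inh0, g_ff0, eta_b0, eta_ff0,
        out_indptr, out_targets, out_weights,
        kernel_seed, spike_times, spike_ids,
    )
    if err == 1:
        raise FloatingPointError(
            "membrane potential diverged; reduce dt or check parameters"
        )
    if err == 2:
        raise RuntimeError(
            f"spike buffer full (> {max_rate_hz} Hz mean rate); "
            "raise max_rate_hz"
        )
    times = spike_times[:n_spikes] - config.t_transient
    ids = spike_ids[:n_spikes]
    trains = [times[ids == i] for i in range(n_total)]
    return SpikeData(trains=trains, n_e=n_e, duration_ms=config.t_measure,
                     theta=theta, seed=config.seed)


def run_tuning_experiment(
    config: RunConfig,
    connectivity: ConnectivityMatrix | None = None,
    disorder=None,
) -> np.ndarray:
    """Mean firing rate (Hz) of every neuron at each stimulus orientation.

    The quenched disorder and connectivity are shared across orientations;
    only the dynamical noise differs.  Returns an array of shape
    (n_neurons, n_orientations) ordered as ``config.orientations``.
    """
    if len(config.orientations) < 4:
        raise ValueError("need at least 4 orientations for tuning curves")
    if connectivity is None:
        connectivity = generate_connectivity(config.topology)
    if disorder is None:
        disorder = network_disorder(config)
    rates = []
    for j, theta in enumerate(config.orientations):
        data = run_trial(config, connectivity, disorder, theta=theta, trial=j)
        rates.append(data.rates_hz())
    return np.column_stack(rates)


def run_fano_experiment(
    config: RunConfig,
    connectivity: ConnectivityMatrix | None = None,
    disorder=None,
    theta: float = 0.0,
    n_trials: int | None = None,
) -> np.ndarray:
    """Per-neuron spike counts over repeated trials with fixed stimulus and
    quenched structure; initial conditions and noise vary per trial.
    Returns an array of shape (n_neurons, n_trials)."""
    n_trials = n_trials or config.n_trials
    if n_trials < 2:
        raise ValueError("need at least two trials")
    if connectivity is None:
        connectivity = generate_connectivity(config.topology)
    if disorder is None:
        disorder = network_disorder(config)
    counts = []
    for trial in range(n_trials):
        data = run_trial(config, connectivity, disorder, theta=theta,
                         trial=trial + 1000)
        counts.append(data.counts())
    return np.column_stack(counts)


def run_reciprocity_sweep(
    config: RunConfig,
    p_values,
    which: str,
    theta: float = 0.0,
    n_fano_trials: int = 0,
    max_lag_ms: float = 200.0,
):
    """Repeat a long measurement trial (and optionally a Fano experiment)
    while sweeping the reciprocity of one connection class ("EE", "II" or
    "EI").  The connectivity is regenerated per p from the same block seeds
    and everything else (disorder, noise paths) is frozen, so differences
    between p values isolate the effect of reciprocity.

    Returns ``{p: {"E": StatsSummary, "I": StatsSummary}}``; when
    ``n_fano_trials >= 2`` each summary also carries per-neuron Fano
    factors.
    """
    from . import stats as st

    disorder = network_disorder(config)
    out = {}
    for p in p_values:
        cfg = config.with_reciprocity(which, p)
        conn = generate_connectivity(cfg.topology)
        data = run_trial(cfg, conn, disorder, theta=theta, trial=0)
        counts = None
        if n_fano_trials >= 2:
            counts = run_fano_experiment(
                cfg, conn, disorder, theta=theta, n_trials=n_fano_trials
            )
        res = {}
        for pop in ("E", "I"):
            summ = st.summarize_population(
                data.population(pop), cfg.t_measure, max_lag_ms=max_lag_ms
            )
            if counts is not None:
                pop_counts = (counts[: cfg.topology.n_e]
                              if pop == "E" else counts[cfg.topology.n_e:])
                ff = np.full(pop_counts.shape[0], np.nan)
                for i, c in enumerate(pop_counts):
                    if c.mean() > 0:
                        ff[i] = st.fano_factor(c)
                summ = replace(summ, fano=ff)
            res[pop] = summ
        out[p] = res
    return out
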