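# Methods

## The model

`recipronet` simulates a two-population (excitatory E, inhibitory I)
recurrent network of conductance-based spiking neurons representing layer
2/3 of rodent primary visual cortex, operating in the balanced state: every
neuron receives on average K excitatory and K inhibitory recurrent inputs
whose strengths scale as G/√K, so that the excitatory and inhibitory drives
are each several times the rheobase and cancel on average, leaving
fluctuation-driven irregular firing.

The distinguishing ingredient is the wiring rule.  Instead of an
independent directed Erdős–Rényi graph, every unordered neuron pair (dyad)
is drawn once from a four-state distribution parameterized by a reciprocity
parameter p per connection class (EE, II, EI):

    P(bidirectional)       = p·K/N + (1−p)·(K/N)²
    P(each unidirectional) = (1−p)·(K/N)·(1 − K/N)

This leaves the expected in-degree (K per class) and hence the mean rates
untouched while raising the expected number of reciprocated partners per
neuron from the chance level K²/N (p = 0, exactly Erdős–Rényi) to pK for
p ≫ K/N.  Reciprocated pairs create length-two loops: a spike returns to
its emitter as a delayed input with integrated weight pKξJ² (ξ the mean
single-neuron gain, J = G/√K), an O(rheobase) effective self-coupling.  Its
sign is positive for EE and (via disinhibition) II loops, negative for
E↔I loops, which is why II reciprocity slows fluctuations and inflates
trial-to-trial variability while EI reciprocity truncates them and produces
an autocorrelation undershoot.

For cross-population dyads with N_E ≠ N_I the two directions have different
marginals c₁ = K/N_E, c₂ = K/N_I; we use P(bidir) = p√(c₁c₂) + (1−p)c₁c₂,
which preserves both marginals and reduces to the within-population formula
at N_E = N_I (the shipped profiles use equal sizes).  Note that full
reciprocity (p = 1) is infeasible when c₁ ≠ c₂; the generator rejects
infeasible combinations.

## Single neurons

One-compartment Hodgkin–Huxley-type dynamics: leak (g_L = 0.1 mS/cm²,
V_L = −65 mV), transient sodium with instantaneous activation
(I_Na = g_Na·m∞³h·(V − V_Na), g_Na = 100 mS/cm², V_Na = 55 mV),
delayed-rectifier potassium (I_K = g_K·n⁴·(V − V_K), g_K = 40 mS/cm²,
V_K = −80 mV), C_m = 1 µF/cm².  Excitatory cells additionally carry an
adaptation current g_adapt·z·(V − V_K) with g_adapt = 0.5 mS/cm²,
z∞(V) = 1/(1 + e^(−0.7(V+30))) and τ_adapt = 60 ms; inhibitory cells have
none.

The h/n rate functions are the Wang–Buzsáki fast-spiking interneuron
kinetics with temperature factor φ = 5, exposed as a pluggable table.  One
deliberate modification: with the high spike conductances above, the
literal Wang–Buzsáki sodium activation leaves no resting fixed point below
−36 mV (the window current exceeds the leak) and the cell fires tonically
with zero input.  We therefore depolarize the m activation curve by +3 mV
(`KineticsTable.m_shift`), which restores a stable rest at ≈ −65 mV, a
rheobase of ≈ 0.3 µA/cm² and a type-I-like f–I curve, while leaving the
spike shape intact.  Setting `m_shift = 0` recovers the textbook kinetics.

## Synapses and external drive

All synaptic currents use a conductance/current mixture with fraction ρ:
I = −g·[ρ(V − V_rev) + (1−ρ)(V_L − V_rev)]; ρ = 0.5 by default (both terms
active; ρ is configurable and results are qualitatively insensitive over
[0, 1]).  Conductances are exponentially filtered spike trains with
τ_syn = 3 ms; each presynaptic spike contributes a transient of unit
integral times ḡ_AB = G_AB/√K with (G_EE, G_IE, G_EI, G_II) =
(0.15, 0.45, 2.0, 3.0) ms·mS/cm².  Excitatory reversal V_E = 0 mV.

The feedforward drive reduces orientation-tuned layer-4 input to a filtered
stochastic rate: mean pool rate c_ff·K·[R₀ + R₁(C)] with c_ff = K_ff/K,
R₀ = 2 Hz, R₁(C) = R₁·log₁₀(C+1), R₁ = 20 Hz, contrast C = 100, plus a
quenched O(√(c_ff K)) per-neuron sample fluctuation whose tuned part is
ξ·z₁ᵢ·cos 2(θ − Δᵢ) with ξ = 0.8, Rayleigh amplitude z₁ᵢ and uniform
preferred orientation Δᵢ (salt-and-pepper, no orientation map).  E cells
receive fewer but stronger feedforward inputs than I cells
(K_ff^E : K_ff^I = 100 : 800 at K = 500, the ratio preserved in reduced
profiles), which is what makes E cells more orientation-selective.  The
rate (plus √rate shot noise) is filtered by the same exponential synapse
with strength ḡ_ff = G_ff/(c_ff√K).

The background drive is an unstructured conductance ḡ_b·K·(R_b +
√(R_b/K)·η(t)) with Ornstein–Uhlenbeck noise η of correlation time τ_syn
and stationary autocovariance e^(−|Δt|/τ_syn)/(2τ_syn) (the unit-integral
exponential kernel, i.e. unit-spectral-density noise; the exact
discretization preserves the stationary law at any step).  Negative
instantaneous rates/conductances are clipped at zero (rare at the shipped
parameters).

### Calibrated values

The strengths of the background and feedforward couplings are not
biophysically constrained by the model structure; they were calibrated
once so that the p = 0 network reproduces the reference operating point
(mean rates ≈ 5 Hz for E, ≈ 9 Hz for I, CV near 1) and then frozen:
G_ff^E = 0.028, G_ff^I = 0.038, G_b = 0.3 (scaled G_b/√K), R_b = 5 Hz,
background noise amplitude 3.0.  The inhibitory reversal was set to
V_I = −80 mV during the same calibration (−75 mV gave a slightly too
depolarized operating point); both are configurable.

## Integration

Exponential Euler for everything, dt = 0.05 ms by default.  At frozen
gating the membrane equation is linear in V, so each step relaxes V exactly
toward the conductance-weighted reversal potential; V can never overshoot
V_Na and the scheme is stable at spike conductances where forward Euler at
the same step overshoots by tens of mV.  Gating variables relax toward
voltage-dependent steady states pre-tabulated on a 0.05 mV grid (linear
interpolation), which keeps them in [0, 1] for any dt.  Spikes are upward
crossings of −20 mV, timed by linear interpolation within the step, with a
2 ms detection lockout (the dynamics are never reset).  Halving dt shifts
spike times of a constant-input cell by ≈ 0.1 ms per spike (a slow phase
drift, first-order in dt).

Seeding: one root seed spawns independent streams for each connectivity
block, the quenched disorder and each trial's noise/initial conditions
(V ~ U[V_L, V_L + 10 mV], gating at steady state).  Sweeping the
reciprocity of one class therefore leaves every other random ingredient
bit-identical, so cross-p differences isolate the wiring effect.

## Statistics

* **OSI** |Σ r(θ_k)e^{2iθ_k}|/Σ r(θ_k); undefined (error), not zero, for a
  silent neuron.
* **Fano factor** population-variance/mean of spike counts over repeated
  trials with fixed stimulus and structure; the counting window is the
  whole measurement window of a trial (recorded in metadata).
* **CV, CV2** population-variance conventions (plain averages); CV2
  averages 2|Δt_{i+1}−Δt_i|/(Δt_{i+1}+Δt_i) over adjacent ISI pairs and is
  insensitive to slow rate modulation.
* **Serial rank correlations** Spearman correlations between ISIs i apart
  (average ranks on ties, default maximum order 20), linked to the Fano
  factor by FF = CV² for renewal trains and FF = CV²(1 + 2Σᵢ SRCᵢ) for
  stationary non-renewal trains.
* **Autocorrelation** 1 ms bins, zero-lag peak removed, estimator
  ⟨N(t)N(t+τ)⟩_t/Δt² whose long-lag limit is the squared rate.  A
  population average converges to the mean of the *squared* rates, which
  exceeds the squared mean rate under rate heterogeneity; the applicable
  asymptote is carried with the function (a rate-normalized display view
  is also provided).
* **Decorrelation time** −1/slope of a linear regression of
  ln(AC − asymptote) on lag, over a window running from the excess peak to
  the larger of 5 % of the peak and twice the tail estimation noise.  If
  the peak excess is below four tail-noise standard deviations the decay
  is reported undefined rather than as an arbitrarily long time constant.
  A literal log-log (power-law slope) variant is available behind a flag.
* **AC undershoot** minimum of AC − asymptote over lags 10–40 ms, past the
  refractory/burst trough that every train shows at short lags.

## Synthetic fixtures

The statistics are validated against point processes with planted
properties, independent of the simulator: Poisson (CV = FF = 1, SRC = 0),
gamma renewal of shape k (CV = 1/√k), a Gaussian-copula AR(1) ISI chain
whose first-order Spearman correlation is set by inverting
ρ_s = (6/π)·asin(a/2) (the oracle for the non-renewal identity), a periodic
train, a rate-modulated locally-regular train (CV inflated, CV2 not) and a
doubly stochastic train with a planted exponential autocorrelation decay.
These fixtures emulate single-train statistics only — they carry no
network correlations, no orientation tuning and no conductance dynamics —
so passing them validates the estimators, not the simulator.

## Problem sizes

The shipped test and acceptance runs use reduced networks chosen so the
whole analysis reruns on a single CPU in minutes: N = 2×500 neurons with
K = 50 (and N = 2×200, K = 20 for smoke tests), measurement windows of
2–10 s and 8–10 Fano trials, versus the full-scale profile (K = 500,
N = 2×10 000, 100 trials) exposed as `RunConfig.full_scale()`.  The
√K scaling keeps the loop self-couplings pKξG² size-independent, so the
qualitative reciprocity effects — which statistic moves, in which
direction, more strongly in which population — are preserved at reduced
scale; their magnitudes (e.g. the quoted ±24 %/−11 % OSI shifts of a
full-scale II sweep) are not expected to match quantitatively, and
direction-of-effect checks at this scale treat signs, not magnitudes, as
the reproducible quantity.

## Known limitations

* The exact rate functions behind the published model's gating are not
  public; the shifted Wang–Buzsáki table is this package's choice, and any
  alternative can be supplied as a `KineticsTable`.
* Reduced-scale runs have larger finite-size fluctuations; the OSI shifts
  under reciprocity sweeps are sign-stable but noisy at N = 2×500.
* Only dyadic reciprocity is controlled; higher-order motif statistics
  follow whatever the dyad-wise draw implies.
* L4 is reduced to a filtered stochastic rate; there are no explicit
  feedforward spikes, no plasticity, no multi-compartment morphology.
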