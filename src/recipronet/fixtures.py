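"""Synthetic spike trains with known statistical structure.

Every statistic in :mod:`recipronet.stats` can be validated against a train
whose properties are planted by construction, without running the network
simulator:

* ``poisson`` — exponential ISIs: CV = 1, FF = 1, all serial correlations 0;
* ``gamma`` — gamma-renewal ISIs with shape k: CV = 1/sqrt(k), FF = CV^2;
* ``markov`` — ISIs with geometric serial rank correlations from a
  Gaussian-copula AR(1) on the ISI quantiles, the oracle for the
  non-renewal identity FF = CV^2 (1 + 2 sum SRC_i);
* ``periodic`` — a clock train: CV = CV2 = 0, FF = 0 over commensurate
  windows;
* ``rate_modulated`` — a locally regular (gamma) train whose rate is slowly
  sinusoidally modulated, for which CV is inflated while CV2 stays low;
* ``exp_cluster`` — a doubly stochastic train whose autocorrelation decays
  exponentially with a planted time constant, for testing decay-time
  recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PointProcessSpec",
    "generate_train",
    "generate_correlated_isis",
    "exp_correlated_train",
    "tiny_network_fixture",
]


@dataclass(frozen=True)
class PointProcessSpec:
    """Family and parameters of one synthetic spike train.

    ``family`` is one of poisson | gamma | markov | periodic |
    rate_modulated.  ``rate_hz`` the mean rate; ``shape`` the gamma shape
    (gamma and rate_modulated); ``serial_corr`` the target first-order ISI
    rank correlation (markov); ``mod_depth``/``mod_period_ms`` the relative
    depth and period of the sinusoidal rate modulation.
    """

    family: str = "poisson"
    rate_hz: float = 10.0
    duration_ms: float = 10_000.0
    shape: float = 1.0
    serial_corr: float = 0.0
    mod_depth: float = 0.5
    mod_period_ms: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in (
            "poisson", "gamma", "markov", "periodic", "rate_modulated"
        ):
            raise ValueError(f"unknown family {self.family!r}")
        if self.rate_hz <= 0 or self.duration_ms <= 0 or self.shape <= 0:
            raise ValueError("rate, duration and shape must be positive")
        if not -1.0 < self.serial_corr < 1.0:
            raise ValueError("serial_corr must lie in (-1, 1)")


def _times_from_isis(isis: np.ndarray, duration: float) -> np.ndarray:
    t = np.cumsum(isis)
    return t[t < duration]


def generate_train(spec: PointProcessSpec) -> np.ndarray:
    """Spike times (ms) on [0, duration) for the given family and seed."""
    rng = np.random.default_rng(spec.seed)
    mean_isi = 1000.0 / spec.rate_hz
    # draw enough ISIs to cover the duration with margin
    n = int(spec.duration_ms / mean_isi * 1.5) + 50
    if spec.family == "poisson":
        isis = rng.exponential(mean_isi, n)
    elif spec.family == "gamma":
        isis = rng.gamma(spec.shape, mean_isi / spec.shape, n)
    elif spec.family == "markov":
        isis = generate_correlated_isis(
            n, spec.serial_corr, rng, mean_isi=mean_isi
        )
    elif spec.family == "periodic":
        isis = np.full(n, mean_isi)
    elif spec.family == "rate_modulated":
        return _rate_modulated_train(spec, rng)
    return _times_from_isis(isis, spec.duration_ms)


def _rate_modulated_train(spec: PointProcessSpec,
                          rng: np.random.Generator) -> np.ndarray:
    """Locally regular gamma train with sinusoidal rate modulation, built by
    time-rescaling a unit-rate gamma renewal process through the integrated
    rate."""
    n = int(spec.duration_ms * spec.rate_hz / 1000.0 * 2.0) + 50
    unit = np.cumsum(rng.gamma(spec.shape, 1.0 / spec.shape, n))
    # invert Lambda(t) = r0 (t - (d P / 2 pi) (cos(2 pi t / P) - 1)) numerically
    r0 = spec.rate_hz / 1000.0
    p = spec.mod_period_ms
    d = spec.mod_depth
    grid = np.linspace(0.0, spec.duration_ms, 200_001)
    lam = r0 * (grid - d * p / (2 * np.pi) * (np.cos(2 * np.pi * grid / p) - 1))
    times = np.interp(unit, lam, grid, right=np.nan)
    return times[np.isfinite(times)]


def generate_correlated_isis(
    n: int,
    rho1: float,
    rng: np.random.Generator | int,
    mean_isi: float = 100.0,
    marginal: str = "exponential",
) -> np.ndarray:
    """ISI sequence with first-order Spearman correlation ~= ``rho1`` and an
    exactly preserved marginal, via a Gaussian-copula AR(1).

    A latent AR(1) Gaussian z_t with coefficient a = 2 sin(pi rho1 / 6)
    (inverting the Gaussian-copula Spearman formula rho_s = (6/pi) asin(a/2))
    is mapped through its own CDF to uniform quantiles and then through the
    inverse CDF of the marginal.  Ranks are invariant under the monotone
    map, so the rank correlations of the latent chain — geometric in the
    order — carry over to the ISIs.
    """
    if not -1.0 < rho1 < 1.0:
        raise ValueError("rho1 must lie in (-1, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    a = 2.0 * np.sin(np.pi * rho1 / 6.0)
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - a * a)
    for i in range(1, n):
        z[i] = a * z[i - 1] + innov[i - 1]
    u = sps.norm.cdf(z)
    if marginal == "exponential":
        isis = -mean_isi * np.log1p(-u)
    elif marginal == "lognormal":
        isis = np.exp(sps.norm.ppf(u)) * mean_isi / np.exp(0.5)
    else:
        raise ValueError(f"unknown marginal {marginal!r}")
    return isis


def exp_correlated_train(
    rate_hz: float,
    tau_ms: float,
    duration_ms: float,
    seed: int,
    mod_depth: float = 0.8,
    dt_ms: float = 1.0,
) -> np.ndarray:
    """Doubly stochastic (Cox) train whose rate is linearly modulated by an
    OU process with correlation time ``tau_ms`` (clipped at zero rate); its
    autocorrelation excess above the squared mean rate decays exponentially
    with approximately the planted time constant."""
    rng = np.random.default_rng(seed)
    n = int(duration_ms / dt_ms)
    a = np.exp(-dt_ms / tau_ms)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - a * a)
    for i in range(1, n):
        x[i] = a * x[i - 1] + innov[i - 1]
    lam = rate_hz * 1e-3 * (1.0 + mod_depth * x)
    lam = np.clip(lam, 0.0, None)
    counts = rng.poisson(lam * dt_ms)
    times = np.repeat(np.arange(n) * dt_ms, counts) + rng.uniform(
        0, dt_ms, counts.sum()
    )
    return np.sort(times)


def tiny_network_fixture(seed: int = 0):
    """A 2 x 200 neuron, K = 20 network configuration that completes a full
    trial in seconds, for end-to-end integration tests.  Returns a
    :class:`recipronet.engine.RunConfig`."""
    from .engine import RunConfig

    return RunConfig.desk_scale(n=200, k=20, seed=seed,
                                t_transient=200.0, t_measure=1000.0)
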