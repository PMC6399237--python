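"""Random two-population connectivity with controlled excess bidirectionality.

In a directed Erdős–Rényi graph the probability that a connection j->i is
reciprocated is just the connection probability K/N.  Cortical circuits show
far more reciprocal (bidirectional) pairs than that chance level.  The wiring
rule implemented here draws every unordered neuron pair ("dyad") once from a
four-state categorical distribution

    P(bidirectional)           = p*K/N + (1-p)*(K/N)^2
    P(each unidirectional dir) = (1-p)*(K/N)*(1 - K/N)
    P(unconnected)             = the remainder,

so that each neuron still receives K inputs on average from each presynaptic
class, while the expected number of reciprocated partners per neuron is
p*K + (1-p)*K^2/N.  At p = 0 the four states factorize and the rule reduces
exactly to the independent Erdős–Rényi graph (chance-level reciprocity
K^2/N bidirectional partners); at p = 1 every realized connection is
reciprocated.

For cross-population (E<->I) dyads with N_E != N_I the two directions have
different marginal probabilities c1 = K/N_E (E->I) and c2 = K/N_I (I->E); we
use P(bidirectional) = p*sqrt(c1*c2) + (1-p)*c1*c2, which preserves both
marginals and reduces to the within-population formula when N_E = N_I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "TopologyConfig",
    "ConnectivityMatrix",
    "MotifCounts",
    "generate_connectivity",
    "count_motifs",
    "dyad_state_probabilities",
    "effective_self_coupling",
]

#: block name -> (postsynaptic population, presynaptic population)
BLOCKS = {"EE": ("E", "E"), "EI": ("E", "I"), "IE": ("I", "E"), "II": ("I", "I")}


@dataclass(frozen=True)
class TopologyConfig:
    """Sizes, target in-degree and per-class reciprocity of the network.

    Parameters
    ----------
    n_e, n_i
        Number of excitatory / inhibitory neurons.
    k
        Target mean in-degree per presynaptic class: every neuron receives on
        average ``k`` excitatory and ``k`` inhibitory recurrent inputs.
    p_ee, p_ii, p_ei
        Reciprocity parameter in [0, 1] for E-E, I-I and E<->I dyads.  The
        chance level (independent graph) is ``k / n`` of the presynaptic
        population; larger values give excess bidirectionality.
    seed
        Root seed; each block is drawn from an independent child stream so
        that e.g. changing ``p_ii`` does not perturb the EE realization.
    """

    n_e: int
    n_i: int
    k: int
    p_ee: float = 0.0
    p_ii: float = 0.0
    p_ei: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_e < 2 or self.n_i < 2:
            raise ValueError("need at least 2 neurons per population")
        if not (0 < self.k <= min(self.n_e, self.n_i)):
            raise ValueError(f"k={self.k} must be in (0, min(n_e, n_i)]")
        for name in ("p_ee", "p_ii", "p_ei"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Four boolean CSR blocks; ``blocks['AB'][i, j]`` means neuron j of
    population B projects to neuron i of population A."""

    blocks: dict[str, sp.csr_matrix]
    config: TopologyConfig = field(compare=False, default=None)

    def __post_init__(self) -> None:
        for name in BLOCKS:
            if name not in self.blocks:
                raise ValueError(f"missing block {name}")

    @property
    def n_e(self) -> int:
        return self.blocks["EE"].shape[0]

    @property
    def n_i(self) -> int:
        return self.blocks["II"].shape[0]

    def in_degrees(self, block: str) -> np.ndarray:
        """Number of presynaptic partners per postsynaptic neuron."""
        return np.asarray(self.blocks[block].sum(axis=1)).ravel()


@dataclass(frozen=True)
class MotifCounts:
    """Exhaustive dyad census of one block pair."""

    n_bidirectional: int
    n_unidirectional: int
    n_unconnected: int

    @property
    def n_dyads(self) -> int:
        return self.n_bidirectional + self.n_unidirectional + self.n_unconnected


def dyad_state_probabilities(
    p: float, k: int, n_1: int, n_2: int | None = None
) -> tuple[float, float, float, float]:
    """Probabilities of the four states of a dyad between a member of
    population 1 (size ``n_1``) and a member of population 2 (size ``n_2``).

    Returns ``(p_bidir, p_uni_from_1, p_uni_from_2, p_none)`` where
    ``p_uni_from_1`` is the probability that only the 1 -> 2 connection is
    present.  The marginal probability of the 1 -> 2 direction is ``k / n_1``
    (the receiving neuron draws its k inputs from the n_1 candidates), and
    symmetrically for 2 -> 1.  Within a population pass ``n_2 = n_1`` (or
    omit it) and the two unidirectional states are exchangeable.

    Raises ``ValueError`` if any state probability would be negative.
    """
    if n_2 is None:
        n_2 = n_1
    c1 = k / n_1  # marginal of the 1 -> 2 direction
    c2 = k / n_2  # marginal of the 2 -> 1 direction
    p_bi = p * np.sqrt(c1 * c2) + (1.0 - p) * c1 * c2
    p_u1 = c1 - p_bi
    p_u2 = c2 - p_bi
    p_none = 1.0 - p_bi - p_u1 - p_u2
    probs = (p_bi, p_u1, p_u2, p_none)
    if any(q < -1e-12 for q in probs):
        raise ValueError(
            f"invalid dyad distribution for p={p}, k={k}, n=({n_1},{n_2}): "
            f"{probs}"
        )
    return tuple(max(q, 0.0) for q in probs)


def _sample_within(
    n: int, k: int, p: float, rng: np.random.Generator
) -> sp.csr_matrix:
    """Draw one within-population block: each unordered pair once from the
    4-state categorical; no self-connections."""
    p_bi, p_u1, p_u2, _ = dyad_state_probabilities(p, k, n)
    iu, ju = np.triu_indices(n, k=1)
    u = rng.random(iu.size)
    bi = u < p_bi
    u1 = (u >= p_bi) & (u < p_bi + p_u1)          # j -> i
    u2 = (u >= p_bi + p_u1) & (u < p_bi + p_u1 + p_u2)  # i -> j
    rows = np.concatenate([iu[bi], ju[bi], iu[u1], ju[u2]])
    cols = np.concatenate([ju[bi], iu[bi], ju[u1], iu[u2]])
    m = sp.csr_matrix(
        (np.ones(rows.size, dtype=np.uint8), (rows, cols)), shape=(n, n)
    )
    return m


def _sample_cross(
    n_e: int, n_i: int, k: int, p: float, rng: np.random.Generator
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Draw the E<->I dyads; returns (C_EI, C_IE).

    ``C_EI[i, j]``: inhibitory j projects to excitatory i (marginal k/n_i);
    ``C_IE[j, i]``: excitatory i projects to inhibitory j (marginal k/n_e).
    """
    # population 1 = E, population 2 = I
    p_bi, p_ei_only, p_ie_only, _ = dyad_state_probabilities(p, k, n_e, n_i)
    u = rng.random((n_e, n_i))
    to_i = u < p_bi + p_ei_only                       # E -> I present
    to_e = (u < p_bi) | (
        (u >= p_bi + p_ei_only) & (u < p_bi + p_ei_only + p_ie_only)
    )                                                 # I -> E present
    c_ei = sp.csr_matrix(to_e.astype(np.uint8))
    c_ie = sp.csr_matrix(to_i.T.astype(np.uint8))
    return c_ei, c_ie


def generate_connectivity(config: TopologyConfig) -> ConnectivityMatrix:
    """Generate the four connectivity blocks for a given reciprocity setting.

    Each block uses an independent child stream of ``config.seed`` so that
    sweeps over one reciprocity class leave the other blocks bit-identical.
    """
    ss = np.random.SeedSequence(config.seed)
    s_ee, s_ii, s_x = ss.spawn(3)
    blocks: dict[str, sp.csr_matrix] = {}
    blocks["EE"] = _sample_within(config.n_e, config.k, config.p_ee,
                                  np.random.default_rng(s_ee))
    blocks["II"] = _sample_within(config.n_i, config.k, config.p_ii,
                                  np.random.default_rng(s_ii))
    blocks["EI"], blocks["IE"] = _sample_cross(
        config.n_e, config.n_i, config.k, config.p_ei,
        np.random.default_rng(s_x)
    )
    return ConnectivityMatrix(blocks=blocks, config=config)


def count_motifs(conn: ConnectivityMatrix, pair: str = "EE") -> MotifCounts:
    """Exhaustive dyad census.

    ``pair`` is ``"EE"`` or ``"II"`` for within-population dyads, or ``"EI"``
    for the cross-population dyads (which involve the EI and IE blocks).
    """
    if pair in ("EE", "II"):
        c = conn.blocks[pair].astype(bool)
        n = c.shape[0]
        n_dyads = n * (n - 1) // 2
        both = c.multiply(c.T)
        n_bi = both.nnz // 2
        n_edges = c.nnz
        n_uni = n_edges - 2 * n_bi
    elif pair == "EI":
        a = conn.blocks["EI"].astype(bool)      # I -> E
        b = conn.blocks["IE"].astype(bool).T    # E -> I, shaped (n_e, n_i)
        n_dyads = a.shape[0] * a.shape[1]
        n_bi = a.multiply(b).nnz
        n_uni = a.nnz + b.nnz - 2 * n_bi
    else:
        raise ValueError(f"unknown dyad pair {pair!r}")
    return MotifCounts(
        n_bidirectional=int(n_bi),
        n_unidirectional=int(n_uni),
        n_unconnected=int(n_dyads - n_bi - n_uni),
    )


def effective_self_coupling(
    p: float,
    k: int,
    gain_e: float,
    gain_i: float,
    j_ee: float = 0.0,
    j_ii: float = 0.0,
    j_ei: float = 0.0,
    j_ie: float = 0.0,
) -> dict[str, float]:
    """Integrated effective self-coupling induced by reciprocated loops.

    A spike of a neuron travels along each of its ~pK length-two loops and
    comes back as a delayed input; with synaptic strengths J = G/sqrt(K) the
    integral of this feedback is O(1).  Signs: loops within one population
    are positive (E-E directly, I-I by disinhibition); E<->I loops are
    negative.

    Returns the loop integrals keyed by ``"EE"``, ``"II"``, ``"EI_on_E"``
    and ``"EI_on_I"``:

    * EE:       +p K xi_E J_EE^2
    * II:       +p K xi_I J_II^2
    * EI on E:  -p K xi_I J_EI J_IE
    * EI on I:  -p K xi_E J_EI J_IE

    where xi_A is the average gain of population A.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if k <= 0 or gain_e < 0 or gain_i < 0:
        raise ValueError("k must be positive and gains nonnegative")
    return {
        "EE": p * k * gain_e * j_ee**2,
        "II": p * k * gain_i * j_ii**2,
        "EI_on_E": -p * k * gain_i * j_ei * j_ie,
        "EI_on_I": -p * k * gain_e * j_ei * j_ie,
    }
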