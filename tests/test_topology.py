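"""Wiring-rule statistics: dyad-state probabilities, in-degree invariance,
motif census and effective self-coupling arithmetic."""

import numpy as np
import pytest
import scipy.sparse as sp

from recipronet.topology import (
    ConnectivityMatrix,
    TopologyConfig,
    count_motifs,
    dyad_state_probabilities,
    effective_self_coupling,
    generate_connectivity,
)


def _conn(n_e=50, n_i=50, k=10, **kw):
    return generate_connectivity(TopologyConfig(n_e=n_e, n_i=n_i, k=k, **kw))


class TestDyadProbabilities:
    def test_zero_p_is_independent_erdos_renyi(self):
        # at p = 0 the dyad states factorize into independent directions
        k, n = 20, 200
        p_bi, p_u1, p_u2, p_none = dyad_state_probabilities(0.0, k, n)
        c = k / n
        assert p_bi == pytest.approx(c * c)
        assert p_u1 == pytest.approx(c * (1 - c))
        assert p_none == pytest.approx((1 - c) ** 2)

    def test_full_p_reciprocates_every_connection(self):
        k, n = 20, 200
        p_bi, p_u1, p_u2, _ = dyad_state_probabilities(1.0, k, n)
        assert p_bi == pytest.approx(k / n)
        assert p_u1 == p_u2 == 0.0

    def test_marginals_preserved_for_any_p(self):
        # feasible p range shrinks when the two populations differ in size
        for p in (0.0, 0.3, 0.6):
            p_bi, p_u1, p_u2, _ = dyad_state_probabilities(p, 30, 300, 600)
            assert p_bi + p_u1 == pytest.approx(30 / 300)
            assert p_bi + p_u2 == pytest.approx(30 / 600)

    def test_rejects_impossible_combination(self):
        # full reciprocity is infeasible when the two marginals differ
        with pytest.raises(ValueError):
            dyad_state_probabilities(1.0, 10, 100, 1000)


class TestGenerateConnectivity:
    def test_fully_reciprocal_block_is_symmetric(self):
        conn = _conn(p_ee=1.0, seed=3)
        ee = conn.blocks["EE"].toarray()
        assert (ee == ee.T).all()
        assert ee.sum() > 0

    def test_no_self_connections(self):
        conn = _conn(seed=1, p_ee=0.5, p_ii=0.5)
        for name in ("EE", "II"):
            assert conn.blocks[name].diagonal().sum() == 0

    def test_reproducible_and_block_seed_isolation(self):
        a = _conn(n_e=100, n_i=100, k=10, p_ii=0.0, seed=5)
        b = _conn(n_e=100, n_i=100, k=10, p_ii=0.8, seed=5)
        # EE and cross blocks identical when only p_ii changes
        assert (a.blocks["EE"] != b.blocks["EE"]).nnz == 0
        assert (a.blocks["EI"] != b.blocks["EI"]).nnz == 0
        assert (a.blocks["IE"] != b.blocks["IE"]).nnz == 0
        assert (a.blocks["II"] != b.blocks["II"]).nnz > 0
        c = _conn(n_e=100, n_i=100, k=10, p_ii=0.8, seed=5)
        assert (b.blocks["II"] != c.blocks["II"]).nnz == 0

    def test_mean_in_degree_invariant_under_p(self):
        # the wiring rule changes reciprocity without changing in-degrees
        n, k = 400, 40
        means = []
        for p in (0.0, 0.5, 1.0):
            conn = _conn(n_e=n, n_i=n, k=k, p_ii=p, seed=11)
            means.append(conn.in_degrees("II").mean())
        se = np.sqrt(k * (1 - k / n) / n)  # SE of the mean in-degree
        for m in means:
            assert abs(m - k) < 4 * se

    def test_bidirectional_partner_count_matches_theory(self):
        # expected reciprocated partners per neuron: pK + (1-p)K^2/N
        n, k, p = 1000, 100, 0.5
        reps = 20
        got = []
        for r in range(reps):
            conn = _conn(n_e=n, n_i=n, k=k, p_ii=p, seed=100 + r)
            m = count_motifs(conn, "II")
            got.append(2 * m.n_bidirectional / n)
        expected = p * k + (1 - p) * k**2 / n  # = 55
        assert expected == pytest.approx(55.0)
        n_dyads = reps * n * (n - 1) / 2
        p_bi = dyad_state_probabilities(p, k, n)[0]
        se_per_neuron = 2 * np.sqrt(n_dyads * p_bi * (1 - p_bi)) / (reps * n)
        assert abs(np.mean(got) - expected) < 3 * se_per_neuron

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TopologyConfig(n_e=10, n_i=10, k=20)
        with pytest.raises(ValueError):
            TopologyConfig(n_e=10, n_i=10, k=5, p_ee=1.2)
        with pytest.raises(ValueError):
            TopologyConfig(n_e=1, n_i=10, k=1)


class TestMotifCensus:
    def _two_neuron(self, edges):
        m = np.zeros((2, 2), dtype=np.uint8)
        for i, j in edges:
            m[i, j] = 1
        blocks = {
            "EE": sp.csr_matrix(m),
            "II": sp.csr_matrix((2, 2), dtype=np.uint8),
            "EI": sp.csr_matrix((2, 2), dtype=np.uint8),
            "IE": sp.csr_matrix((2, 2), dtype=np.uint8),
        }
        return ConnectivityMatrix(blocks=blocks)

    def test_reciprocal_pair(self):
        m = count_motifs(self._two_neuron([(0, 1), (1, 0)]), "EE")
        assert (m.n_bidirectional, m.n_unidirectional) == (1, 0)

    def test_single_edge(self):
        m = count_motifs(self._two_neuron([(0, 1)]), "EE")
        assert (m.n_bidirectional, m.n_unidirectional, m.n_unconnected) == \
            (0, 1, 0)

    def test_empty_block_all_unconnected(self):
        m = count_motifs(self._two_neuron([]), "EE")
        assert m.n_unconnected == m.n_dyads == 1

    def test_er_block_bidirectional_fraction(self):
        n, k = 200, 20
        reps = 30
        frac = []
        for r in range(reps):
            conn = _conn(n_e=n, n_i=n, k=k, p_ee=0.0, seed=r)
            m = count_motifs(conn, "EE")
            frac.append(m.n_bidirectional / m.n_dyads)
        c = k / n
        se = np.sqrt(c**2 * (1 - c**2) / (reps * n * (n - 1) / 2))
        assert abs(np.mean(frac) - c**2) < 3 * se

    def test_census_is_exhaustive(self):
        conn = _conn(n_e=80, n_i=60, k=15, p_ei=0.4, seed=2)
        m = count_motifs(conn, "EI")
        assert m.n_dyads == 80 * 60


class TestEffectiveSelfCoupling:
    def test_zero_reciprocity_gives_zero(self):
        out = effective_self_coupling(0.0, 500, 1.0, 1.0, j_ee=0.1, j_ii=0.2,
                                      j_ei=0.3, j_ie=0.1)
        assert all(v == 0 for v in out.values())

    def test_loop_integrals_and_signs(self):
        k = 500
        j_ii = 3.0 / np.sqrt(k)  # G_II / sqrt(K)
        out = effective_self_coupling(0.5, k, gain_e=2.0, gain_i=1.0,
                                      j_ee=0.1, j_ii=j_ii, j_ei=0.4, j_ie=0.2)
        assert out["II"] == pytest.approx(4.5)  # 0.5 * 500 * (3/sqrt(500))^2
        assert out["EE"] == pytest.approx(0.5 * 500 * 2.0 * 0.1**2)
        assert out["EI_on_E"] == pytest.approx(-0.5 * 500 * 1.0 * 0.4 * 0.2)
        assert out["EI_on_I"] == pytest.approx(-0.5 * 500 * 2.0 * 0.4 * 0.2)
        assert out["EE"] > 0 and out["II"] > 0
        assert out["EI_on_E"] < 0 and out["EI_on_I"] < 0
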