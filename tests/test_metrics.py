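"""Graph-metric correctness against closed forms and brute-force oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nirsnet as nn
from nirsnet.core import BinaryGraph

import oracles


def _complete(n):
    a = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(a, 0)
    return a


def _path3():
    # a - b - c
    return np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8)


class TestClosedForms:
    def test_path_graph_distances(self):
        d = nn.shortest_paths(_path3())
        assert d[0, 2] == 2 and d[0, 1] == 1 and d[0, 0] == 0

    def test_complete_graph_distances(self):
        d = nn.shortest_paths(_complete(4))
        off = d[~np.eye(4, dtype=bool)]
        assert (off == 1).all()

    def test_triangle_fully_clustered(self):
        c_p, c_i = nn.clustering_coefficient(_complete(3))
        assert c_p == 1.0 and (c_i == 1.0).all()

    def test_star_unclustered(self):
        star = np.zeros((4, 4), dtype=np.int8)
        star[0, 1:] = star[1:, 0] = 1
        c_p, _ = nn.clustering_coefficient(star)
        assert c_p == 0.0

    def test_lp_of_complete_graph(self):
        assert nn.characteristic_path_length(nn.shortest_paths(_complete(5))) == 1.0

    def test_lp_of_path_graph(self):
        assert nn.characteristic_path_length(nn.shortest_paths(_path3())) == pytest.approx(4 / 3)

    def test_lp_disjoint_dumbbells_uses_reachable_pairs_only(self):
        # two disjoint K2 components: all reachable distances are 1
        adj = np.zeros((4, 4), dtype=np.int8)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        assert nn.characteristic_path_length(nn.shortest_paths(adj)) == 1.0

    def test_lp_undefined_for_edgeless(self):
        assert np.isnan(nn.characteristic_path_length(nn.shortest_paths(np.zeros((5, 5), dtype=np.int8))))

    def test_efficiency_of_k3(self):
        e_glob, _ = nn.nodal_and_global_efficiency(nn.shortest_paths(_complete(3)))
        assert e_glob == 1.0

    def test_efficiency_of_path_graph(self):
        e_glob, e_nodal = nn.nodal_and_global_efficiency(nn.shortest_paths(_path3()))
        assert e_nodal[1] == 1.0
        assert e_nodal[0] == pytest.approx(0.75)
        assert e_glob == pytest.approx(5 / 6)

    def test_efficiency_of_disconnected_graph(self):
        e_glob, _ = nn.nodal_and_global_efficiency(nn.shortest_paths(np.zeros((6, 6), dtype=np.int8)))
        assert e_glob == 0.0

    def test_local_efficiency_of_k4(self):
        e_loc, _ = nn.local_efficiency(_complete(4))
        assert e_loc == 1.0

    def test_local_efficiency_of_star(self):
        star = np.zeros((5, 5), dtype=np.int8)
        star[0, 1:] = star[1:, 0] = 1
        e_loc, _ = nn.local_efficiency(star)
        assert e_loc == 0.0

    def test_betweenness_of_path_graph(self):
        bc = nn.betweenness(_path3())
        assert bc[1] == 1.0 and bc[0] == bc[2] == 0.0

    def test_betweenness_of_complete_graph(self):
        assert (nn.betweenness(_complete(4)) == 0.0).all()

    def test_all_metrics_on_k12(self):
        m = nn.all_metrics(_complete(12))
        assert m.c_p == m.l_p == m.e_glob == m.e_loc == 1.0
        assert (m.k_nodal == 11).all()

    def test_all_metrics_on_edgeless_graph(self):
        m = nn.all_metrics(np.zeros((12, 12), dtype=np.int8))
        assert m.c_p == m.e_glob == m.e_loc == 0.0
        assert np.isnan(m.l_p)
        assert (m.k_nodal == 0).all()

    def test_ring_lattice_clustering_closed_form(self):
        # Watts-Strogatz at p=0, k=4: C = 3(k-2)/(4(k-1)) = 0.5
        adj = nx.to_numpy_array(nx.watts_strogatz_graph(12, 4, 0.0)).astype(np.int8)
        m = nn.all_metrics(adj)
        assert m.c_p == pytest.approx(0.5)


class TestOracleEquivalence:
    """Every metric equals its independent brute-force oracle on small graphs."""

    @pytest.mark.parametrize("seed", range(40))
    def test_random_graphs_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 9)
        adj = oracles.random_adjacency(rng, n)
        d = nn.shortest_paths(adj)
        d_oracle = oracles.floyd_warshall(adj)
        assert np.array_equal(d, d_oracle)

        c_p, c_i = nn.clustering_coefficient(adj)
        c_p_o, c_i_o = oracles.clustering_by_triples(adj)
        np.testing.assert_allclose(c_i, c_i_o, atol=1e-12)

        l_p = nn.characteristic_path_length(d)
        l_p_o = oracles.path_length_mean(d_oracle)
        assert (np.isnan(l_p) and np.isnan(l_p_o)) or l_p == pytest.approx(l_p_o, abs=1e-12)

        e_g, e_n = nn.nodal_and_global_efficiency(d)
        e_g_o, e_n_o = oracles.efficiency_from_dist(d_oracle)
        np.testing.assert_allclose(e_n, e_n_o, atol=1e-12)

        e_l, e_ln = nn.local_efficiency(adj)
        e_l_o, e_ln_o = oracles.local_efficiency_oracle(adj)
        np.testing.assert_allclose(e_ln, e_ln_o, atol=1e-12)

        np.testing.assert_allclose(
            nn.betweenness(adj), oracles.betweenness_by_enumeration(adj), atol=1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_betweenness_matches_networkx(self, seed):
        adj = oracles.random_adjacency(np.random.default_rng(seed), 10)
        ours = nn.betweenness(adj)
        theirs = nx.betweenness_centrality(nx.from_numpy_array(adj), normalized=False)
        np.testing.assert_allclose(ours, [theirs[i] for i in range(10)], atol=1e-9)


class TestInvariants:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_relabeling_invariance(self, seed):
        """Global metrics are invariant under node permutation; nodal vectors permute."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        adj = oracles.random_adjacency(rng, n)
        perm = rng.permutation(n)
        padj = adj[np.ix_(perm, perm)]
        m, pm = nn.all_metrics(adj), nn.all_metrics(padj)
        for name in ("c_p", "e_glob", "e_loc"):
            assert getattr(m, name) == pytest.approx(getattr(pm, name), abs=1e-12)
        if np.isnan(m.l_p):
            assert np.isnan(pm.l_p)
        else:
            assert m.l_p == pytest.approx(pm.l_p, abs=1e-12)
        np.testing.assert_allclose(pm.k_nodal, m.k_nodal[perm], atol=1e-12)
        np.testing.assert_allclose(pm.n_bc, m.n_bc[perm], atol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_edge_addition_monotonicity(self, seed):
        """Adding an edge never increases a distance; E_glob never decreases."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        adj = oracles.random_adjacency(rng, n, p=0.4)
        missing = [(i, j) for i in range(n) for j in range(i + 1, n) if not adj[i, j]]
        if not missing:
            return
        i, j = missing[rng.integers(len(missing))]
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = 1
        d1, d2 = nn.shortest_paths(adj), nn.shortest_paths(adj2)
        assert (d2 <= d1 + 1e-12).all()
        assert nn.nodal_and_global_efficiency(d2)[0] >= nn.nodal_and_global_efficiency(d1)[0] - 1e-12

    @pytest.mark.parametrize("seed", range(15))
    def test_metric_ranges(self, seed):
        rng = np.random.default_rng(seed)
        m = nn.all_metrics(oracles.random_adjacency(rng, int(rng.integers(3, 13))))
        assert 0.0 <= m.c_p <= 1.0
        assert 0.0 <= m.e_glob <= 1.0 and 0.0 <= m.e_loc <= 1.0
        assert np.isnan(m.l_p) or m.l_p >= 1.0
        assert (m.n_bc >= 0).all()
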