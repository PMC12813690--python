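"""Graph topology metrics, degree-preserving nulls, small-world
normalization, and AUC summaries."""

import warnings

import numpy as np
import pytest

from connectoscope.connectome import BinaryGraph, graph_series
from connectoscope.graph_metrics import (connectome_curves, global_metrics,
                                         metric_auc, modularity_q,
                                         nodal_metrics,
                                         normalized_small_world, rewire_null,
                                         shortest_paths)
from oracles import (bf_betweenness, bf_char_path, bf_global_efficiency,
                     bf_local_efficiency, bf_modularity,
                     bf_nodal_clustering, bf_nodal_efficiency, bf_nodal_path,
                     fw_distances)


def graph_of(adj):
    adj = np.asarray(adj, bool)
    return BinaryGraph(adj, 0.5, int(adj.sum()) // 2)


def complete(n):
    a = np.ones((n, n), bool)
    np.fill_diagonal(a, False)
    return graph_of(a)


def path(n):
    a = np.zeros((n, n), bool)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = True
    return graph_of(a)


def star(leaves):
    a = np.zeros((leaves + 1, leaves + 1), bool)
    a[0, 1:] = a[1:, 0] = True
    return graph_of(a)


class TestClosedForms:
    def test_k5_is_maximally_efficient(self):
        gm = global_metrics(complete(5))
        assert (gm.Cp, gm.Lp, gm.Eglobal, gm.Elocal) == (1.0, 1.0, 1.0, 1.0)
        nm = nodal_metrics(complete(5))
        assert (nm["betweenness"] == 0).all()
        assert (nm["nodal_cp"] == 1).all()

    def test_p3_global_efficiency(self):
        gm = global_metrics(path(3))
        assert gm.Eglobal == pytest.approx((1 + 1 + 0.5) / 3)
        assert gm.Cp == 0.0

    def test_star_center_betweenness(self):
        nm = nodal_metrics(star(4))
        assert nm["betweenness"][0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert (nm["betweenness"][1:] == 0).all()

    def test_two_disjoint_k4_modularity(self):
        a = np.zeros((8, 8), bool)
        a[:4, :4] = ~np.eye(4, dtype=bool)
        a[4:, 4:] = ~np.eye(4, dtype=bool)
        assert modularity_q(graph_of(a)) == pytest.approx(0.5)

    def test_chain_and_disconnection_distances(self):
        d = shortest_paths(path(3))
        assert d[0, 2] == 2
        a = np.zeros((4, 4), bool)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = True
        d = shortest_paths(graph_of(a))
        assert np.isinf(d[0, 2])


class TestBruteForceEquivalence:
    def test_random_small_graphs_match_oracle_exactly(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 7))
            adj = rng.random((n, n)) < 0.5
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            g = graph_of(adj)
            A = adj.astype(int).tolist()
            dist = shortest_paths(g)
            ref = np.array(fw_distances(A))
            assert np.array_equal(dist, ref)
            gm = global_metrics(g, dist=dist)
            nm = nodal_metrics(g, dist=dist)
            if g.edge_count:
                assert gm.Eglobal == pytest.approx(bf_global_efficiency(A),
                                                   abs=1e-12)
                assert gm.Lp == pytest.approx(bf_char_path(A), abs=1e-12)
            assert np.allclose(nm["betweenness"], bf_betweenness(A), atol=1e-12)
            assert np.allclose(nm["nodal_cp"], bf_nodal_clustering(A),
                               atol=1e-12)
            assert np.allclose(nm["nodal_efficiency"], bf_nodal_efficiency(A),
                               atol=1e-12)
            assert np.allclose(nm["nodal_local_efficiency"],
                               bf_local_efficiency(A), atol=1e-12)
            assert np.allclose(nm["nodal_shortest_path"], bf_nodal_path(A),
                               atol=1e-12)

    def test_greedy_modularity_at_least_trivial_partition(self, rng):
        for seed in range(8):
            r = np.random.default_rng(seed)
            adj = r.random((12, 12)) < 0.3
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            g = graph_of(adj)
            q = modularity_q(g)
            assert q >= -1e-12  # one-community partition has Q = 0
            if g.edge_count:
                # never exceeds the best partition's bound of 1
                assert q <= 1.0


class TestRewireNull:
    def test_degree_sequence_and_edge_count_preserved(self, subject_matrix):
        g = graph_series(subject_matrix)[20]
        null = rewire_null(g, seed=5)
        assert null.edge_count == g.edge_count
        assert (null.adjacency.sum(1) == g.adjacency.sum(1)).all()
        assert not null.adjacency.diagonal().any()
        assert (null.adjacency != g.adjacency).any()

    def test_triangle_cannot_be_rewired(self):
        a = np.zeros((3, 3), bool)
        a[0, 1] = a[1, 2] = a[0, 2] = True
        a = a | a.T
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            out = rewire_null(graph_of(a), seed=0)
        assert any("swap" in str(w.message) for w in caught)
        assert (out.adjacency == (a | a.T)).all()

    def test_deterministic_for_fixed_seed(self, subject_matrix):
        g = graph_series(subject_matrix)[30]
        assert (rewire_null(g, seed=3).adjacency
                == rewire_null(g, seed=3).adjacency).all()


class TestSmallWorldNormalization:
    def test_sigma_is_gamma_over_lambda(self, subject_matrix):
        g = graph_series(subject_matrix)[10]
        gamma, lam, sigma = normalized_small_world(g, n_rand=3, seed=0)
        assert sigma == pytest.approx(gamma / lam, abs=1e-12)

    def test_random_graph_is_its_own_null(self, rng):
        # dense Erdos-Renyi at the sparsity-0.3 edge count: rewired nulls
        # have the same statistics, so gamma ~ 1 and lambda ~ 1
        n, m = 90, int(0.3 * 4005)
        iu, ju = np.triu_indices(n, 1)
        pick = rng.choice(len(iu), m, replace=False)
        a = np.zeros((n, n), bool)
        a[iu[pick], ju[pick]] = True
        a = a | a.T
        gamma, lam, _ = normalized_small_world(graph_of(a), n_rand=5, seed=1)
        assert 0.8 < gamma < 1.2
        assert 0.95 < lam < 1.05

    def test_ring_lattice_is_small_world_after_slight_rewiring(self):
        # Watts-Strogatz construction: high clustering survives, paths
        # shorten toward the random graph -> sigma > 1
        n, k = 90, 10
        a = np.zeros((n, n), bool)
        for i in range(n):
            for d in range(1, k // 2 + 1):
                a[i, (i + d) % n] = a[(i + d) % n, i] = True
        g = rewire_null(graph_of(a), n_swaps=45, seed=2)  # 10% perturbation
        _, _, sigma = normalized_small_world(g, n_rand=5, seed=3)
        assert sigma > 1.0

    def test_empty_graph_rejected(self):
        empty = BinaryGraph(np.zeros((5, 5), bool), 0.1, 0)
        with pytest.raises(ValueError):
            normalized_small_world(empty, n_rand=2, seed=0)


class TestMetricAuc:
    def test_constant_curve_area(self):
        grid = np.round(np.arange(0.05, 0.501, 0.01), 2)
        assert metric_auc(np.full(46, 2.0), grid) == pytest.approx(0.9)
        assert metric_auc(np.full(46, 1.0), grid) == pytest.approx(0.45)

    def test_linear_curve_closed_form(self):
        grid = np.round(np.arange(0.05, 0.501, 0.01), 2)
        assert metric_auc(grid, grid) == pytest.approx((0.5 ** 2 - 0.05 ** 2) / 2)

    def test_single_interval_trapezoid(self):
        assert metric_auc(np.array([1.0, 3.0]),
                          np.array([0.05, 0.06])) == pytest.approx(0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metric_auc(np.ones(5), np.ones(4))


class TestConnectomeCurves:
    def test_shapes_and_determinism(self, subject_matrix):
        graphs = graph_series(subject_matrix)[:5]
        a = connectome_curves(graphs, n_rand=2, seed=7)
        b = connectome_curves(graphs, n_rand=2, seed=7)
        assert a.global_curves.shape == (5, 8)
        assert a.nodal_auc.shape == (90, 6)
        assert np.allclose(a.global_curves.to_numpy(),
                           b.global_curves.to_numpy())
        assert np.allclose(a.global_curves["sigma"],
                           a.global_curves["gamma"] / a.global_curves["lambda"],
                           atol=1e-12)

    def test_eglobal_monotone_under_edge_addition(self, subject_matrix):
        graphs = graph_series(subject_matrix)
        eglob = [global_metrics(g).Eglobal for g in graphs[::9]]
        assert all(a <= b + 1e-12 for a, b in zip(eglob, eglob[1:]))

    def test_isomorphism_invariance(self, rng):
        adj = rng.random((10, 10)) < 0.4
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        perm = rng.permutation(10)
        g1, g2 = graph_of(adj), graph_of(adj[np.ix_(perm, perm)])
        gm1, gm2 = global_metrics(g1), global_metrics(g2)
        for field in ("Eglobal", "Elocal", "Cp", "Lp"):
            assert getattr(gm1, field) == pytest.approx(getattr(gm2, field),
                                                        abs=1e-12)
        nm1, nm2 = nodal_metrics(g1), nodal_metrics(g2)
        for col in nm1.columns:
            assert np.allclose(nm1[col].to_numpy()[perm], nm2[col].to_numpy(),
                               atol=1e-12)
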