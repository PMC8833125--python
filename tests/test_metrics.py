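import inspect

import numpy as np
import pytest

from metabonet import (auc_over_grid, betweenness_centrality, build_stack,
                       characteristic_path_length, clustering_coefficient,
                       default_grid, distance_matrix, global_efficiency,
                       global_metrics, group_correlation, local_efficiency,
                       nodal_efficiency, node_degree,
                       rewire_degree_preserving, small_world)
from metabonet.metrics import global_curves_from_stack, nodal_curves_from_stack
from metabonet.network import SparsityGrid
from oracles import (bfs_distances, oracle_betweenness, oracle_clustering,
                     oracle_degree, oracle_eglob, oracle_eloc, oracle_enod,
                     oracle_lp, random_graph)


def complete(n):
    return ~np.eye(n, dtype=bool)


def cycle(n):
    a = np.zeros((n, n), dtype=bool)
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = True
    return a


def path(n):
    a = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = True
    return a


def star(n_leaves):
    a = np.zeros((n_leaves + 1, n_leaves + 1), dtype=bool)
    a[0, 1:] = a[1:, 0] = True
    return a


class TestClosedForms:
    def test_complete_graph_k4(self):
        k4 = complete(4)
        assert characteristic_path_length(k4) == 1.0
        assert clustering_coefficient(k4)[1] == 1.0
        assert global_efficiency(k4) == 1.0
        assert local_efficiency(k4)[1] == 1.0
        np.testing.assert_array_equal(node_degree(k4), [3, 3, 3, 3])
        np.testing.assert_allclose(nodal_efficiency(k4), 1.0)

    def test_cycle_c5(self):
        c5 = cycle(5)
        assert characteristic_path_length(c5) == pytest.approx(1.5)
        assert global_efficiency(c5) == pytest.approx(0.75)

    def test_path_p4(self):
        assert characteristic_path_length(path(4)) == pytest.approx(10 / 6)

    def test_star_graph(self):
        s = star(5)
        assert clustering_coefficient(s)[1] == 0.0
        bc = betweenness_centrality(s)
        assert bc[0] == pytest.approx(10.0)  # C(5, 2) pairs route via hub
        np.testing.assert_allclose(bc[1:], 0.0)
        enod = nodal_efficiency(star(4))
        assert enod[0] == pytest.approx(1.0)
        assert enod[1] == pytest.approx((1 + 3 * 0.5) / 4)

    def test_path_p3_betweenness(self):
        bc = betweenness_centrality(path(3))
        np.testing.assert_allclose(bc, [0.0, 1.0, 0.0])

    def test_two_disjoint_edges(self):
        a = np.zeros((4, 4), dtype=bool)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = True
        assert global_efficiency(a) == pytest.approx(1 / 3)
        assert characteristic_path_length(a) == pytest.approx(1.0)

    def test_triangle_plus_pendant(self):
        a = np.zeros((4, 4), dtype=bool)
        for i, j in [(0, 1), (0, 2), (1, 2), (0, 3)]:
            a[i, j] = a[j, i] = True
        per, cp = clustering_coefficient(a)
        np.testing.assert_allclose(per, [1 / 3, 1.0, 1.0, 0.0])
        assert cp == pytest.approx(7 / 12)
        per_e, eloc = local_efficiency(a)
        np.testing.assert_allclose(per_e, oracle_eloc(a)[0])
        assert eloc == pytest.approx(oracle_eloc(a)[1])

    def test_undefined_markers(self):
        empty = np.zeros((3, 3), dtype=bool)
        assert np.isnan(characteristic_path_length(empty))
        assert global_efficiency(empty) == 0.0


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(3, 11))
            a = random_graph(rng, n)
            np.testing.assert_array_equal(node_degree(a), oracle_degree(a))
            np.testing.assert_allclose(betweenness_centrality(a),
                                       oracle_betweenness(a), atol=1e-9)
            olp = oracle_lp(a)
            lp = characteristic_path_length(a)
            if np.isnan(olp):
                assert np.isnan(lp)
            else:
                assert lp == pytest.approx(olp, abs=1e-12)
            assert global_efficiency(a) == pytest.approx(oracle_eglob(a), abs=1e-12)
            np.testing.assert_allclose(nodal_efficiency(a), oracle_enod(a),
                                       atol=1e-12)
            np.testing.assert_allclose(clustering_coefficient(a)[0],
                                       oracle_clustering(a)[0], atol=1e-12)
            np.testing.assert_allclose(local_efficiency(a)[0],
                                       oracle_eloc(a)[0], atol=1e-12)

    def test_distance_matrix_vs_bfs_and_scipy(self):
        from scipy.sparse.csgraph import shortest_path
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = random_graph(rng, int(rng.integers(4, 15)))
            d = distance_matrix(a)
            np.testing.assert_array_equal(d, np.asarray(bfs_distances(a)))
            np.testing.assert_array_equal(
                d, shortest_path(a.astype(np.int8), method="D", unweighted=True))

    def test_isomorphism_invariance(self):
        rng = np.random.default_rng(12)
        a = random_graph(rng, 9)
        perm = rng.permutation(9)
        b = a[np.ix_(perm, perm)]
        assert characteristic_path_length(a) == pytest.approx(
            characteristic_path_length(b), abs=1e-12)
        assert clustering_coefficient(a)[1] == pytest.approx(
            clustering_coefficient(b)[1], abs=1e-12)
        np.testing.assert_allclose(betweenness_centrality(a)[perm],
                                   betweenness_centrality(b), atol=1e-9)
        np.testing.assert_allclose(nodal_efficiency(a)[perm],
                                   nodal_efficiency(b), atol=1e-12)

    def test_handshake_identity(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            a = random_graph(rng, int(rng.integers(3, 20)))
            assert node_degree(a).sum() == a.sum()


class TestRewiring:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(20)
        for s in range(10):
            a = random_graph(rng, 12, p=0.3)
            b = rewire_degree_preserving(a, seed=s)
            np.testing.assert_array_equal(node_degree(a), node_degree(b))
            assert (b == b.T).all() and not b.diagonal().any()

    def test_complete_graph_returned_unchanged(self):
        with pytest.warns(UserWarning, match="no degree-preserving swap"):
            out = rewire_degree_preserving(complete(4), seed=0)
        np.testing.assert_array_equal(out, complete(4))

    def test_cycle_rewires_with_high_probability(self):
        c8 = cycle(8)
        changed = sum(
            not np.array_equal(rewire_degree_preserving(c8, seed=s), c8)
            for s in range(20))
        assert changed >= 15

    def test_seed_determinism(self):
        a = random_graph(np.random.default_rng(21), 15, p=0.4)
        b1 = rewire_degree_preserving(a, seed=5)
        b2 = rewire_degree_preserving(a, seed=5)
        b3 = rewire_degree_preserving(a, seed=6)
        np.testing.assert_array_equal(b1, b2)
        assert not np.array_equal(b1, b3)


class TestSmallWorld:
    def test_sigma_identity(self):
        rng = np.random.default_rng(30)
        a = random_graph(rng, 20, p=0.25)
        sw = small_world(a, ensemble_size=10, seed=1)
        assert sw.sigma == sw.gamma / sw.lam

    def test_default_ensemble_size(self):
        assert inspect.signature(small_world).parameters["ensemble_size"].default == 5000

    def test_self_null_calibration_on_random_graph(self):
        # an Erdos-Renyi-like graph is its own null: gamma and lambda ~ 1
        rng = np.random.default_rng(31)
        a = random_graph(rng, 24, p=0.3)
        sw = small_world(a, ensemble_size=200, seed=2)
        _, cp = clustering_coefficient(a)
        # 3 standard errors of the ensemble
        se_gamma = 3 * cp / sw.ensemble.mean_Cp_rand / np.sqrt(200)
        assert abs(sw.gamma - 1) < max(3 * se_gamma, 0.2)
        assert abs(sw.lam - 1) < 0.1

    def test_ensemble_preserves_degrees(self, null_table):
        net = group_correlation(null_table, "aged")
        stack = build_stack(net)
        adj = stack.adjacencies[5]
        deg = node_degree(adj)
        for s in range(5):
            np.testing.assert_array_equal(
                node_degree(rewire_degree_preserving(adj, seed=s)), deg)


class TestAUC:
    def test_constant_curve_over_default_grid(self):
        grid = default_grid()
        assert auc_over_grid(np.full(46, 2.5), grid) == pytest.approx(2.5 * 0.45)

    def test_identity_ramp_closed_form(self):
        grid = default_grid()
        assert auc_over_grid(grid.as_array(), grid) == pytest.approx(
            (0.5**2 - 0.05**2) / 2)

    def test_two_point_trapezoid(self):
        assert auc_over_grid([1.0, 3.0], SparsityGrid((0.1, 0.2))) == pytest.approx(0.2)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            auc_over_grid([1.0], np.array([0.1]))

    def test_nan_dropped_pairwise_with_warning(self):
        grid = SparsityGrid((0.1, 0.2, 0.3))
        with pytest.warns(UserWarning, match="dropping"):
            v = auc_over_grid([1.0, np.nan, 1.0], grid)
        assert v == pytest.approx(0.2)


class TestCurves:
    def test_eglob_monotone_over_nested_stack(self, null_table):
        net = group_correlation(null_table, "young")
        stack = build_stack(net)
        curves = global_curves_from_stack(stack, ("Eglob",))
        assert (np.diff(curves["Eglob"]) >= -1e-12).all()

    def test_nodal_curve_shapes_and_degree_row_sums(self, null_table):
        net = group_correlation(null_table, "aged")
        stack = build_stack(net)
        curves = nodal_curves_from_stack(stack, ("D",))
        assert curves["D"].shape == (46, 96)
        np.testing.assert_array_equal(curves["D"].sum(1) / 2, stack.edge_counts())
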