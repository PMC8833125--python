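import numpy as np
import pytest

from conftest import make_table
from metabonet import (GroupNetwork, SparsityGrid, build_stack, default_grid,
                       group_correlation, min_density_connected,
                       threshold_sparsity)
from metabonet.network import iter_stack, ranked_edges
from metabonet.permtest import _corr
from oracles import oracle_min_density_k, oracle_pearson


def net_from_matrix(m, n_subjects=10):
    return GroupNetwork(matrix=np.asarray(m, dtype=float), group_id="g",
                        n_subjects=n_subjects)


class TestGroupCorrelation:
    def test_duplicated_region_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 1))
        vals = np.hstack([base, base, rng.normal(size=(6, 2))])
        t = make_table(vals, ["a"] * 6)
        net = group_correlation(t, "a")
        assert net.matrix[0, 1] == pytest.approx(1.0)

    def test_negated_region_gives_minus_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 1))
        vals = np.hstack([base, -base, rng.normal(size=(6, 2))])
        t = make_table(vals, ["a"] * 6)
        assert group_correlation(t, "a").matrix[0, 1] == pytest.approx(-1.0)

    def test_three_subject_toy_hand_value(self):
        # x=(1,2,3), y=(2,1,4): cov-sum 2, var-sums 2 and 14/3, so by the
        # definition formula r = 2 / sqrt(2 * 14/3)
        x = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0]])
        m = _corr(x)
        assert m[0, 1] == pytest.approx(2 / np.sqrt(2 * 14 / 3), abs=1e-12)
        assert m[0, 1] == pytest.approx(oracle_pearson([1, 2, 3], [2, 1, 4]),
                                        abs=1e-12)

    def test_zero_variance_region_named(self):
        vals = np.column_stack([np.ones(6), np.arange(6.0), np.arange(6.0) ** 2])
        t = make_table(vals, ["a"] * 6, columns=["flat", "x", "y"])
        with pytest.raises(ValueError, match="flat"):
            group_correlation(t, "a")

    def test_matches_from_definition_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n_sub = rng.integers(4, 12)
            n_reg = rng.integers(3, 8)
            vals = rng.normal(size=(n_sub, n_reg))
            t = make_table(vals, ["a"] * n_sub)
            net = group_correlation(t, "a")
            for i in range(n_reg):
                for j in range(i + 1, n_reg):
                    expect = oracle_pearson(vals[:, i], vals[:, j])
                    assert net.matrix[i, j] == pytest.approx(expect, abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(8, 6))
        t = make_table(vals, ["a"] * 8)
        perm = rng.permutation(6)
        t2 = make_table(vals[:, perm], ["a"] * 8)
        m1 = group_correlation(t, "a").matrix
        m2 = group_correlation(t2, "a").matrix
        np.testing.assert_allclose(m2, m1[np.ix_(perm, perm)], atol=1e-15)

    def test_too_few_subjects_refused(self):
        t = make_table(np.random.default_rng(4).normal(size=(3, 5)), ["a"] * 3)
        with pytest.raises(ValueError, match=">= 4"):
            group_correlation(t, "a")


@pytest.fixture(scope="module")
def net96(null_table):
    return group_correlation(null_table, "aged")


class TestThresholding:
    @pytest.mark.parametrize("s,expected", [(0.05, 228), (0.50, 2280),
                                            (0.10, 456), (0.37, 1687)])
    def test_edge_counts_exact(self, net96, s, expected):
        adj = threshold_sparsity(net96, s)
        assert int(adj.sum()) // 2 == expected

    def test_full_grid_edge_counts_and_nesting(self, net96):
        stack = build_stack(net96)
        assert len(stack.adjacencies) == 46
        prev = None
        for s, adj, count in zip(stack.grid, stack.adjacencies, stack.edge_counts()):
            assert count == int(np.floor(s * 4560 + 0.5))
            assert (adj == adj.T).all() and not adj.diagonal().any()
            if prev is not None:
                assert (adj | prev == adj).all()  # edges only ever added
            prev = adj

    def test_matches_single_threshold(self, net96):
        stack = build_stack(net96)
        for li in (0, 20, 45):
            np.testing.assert_array_equal(
                stack.adjacencies[li],
                threshold_sparsity(net96, stack.grid.values[li]))

    def test_iter_stack_agrees_with_build_stack(self, net96):
        stack = build_stack(net96)
        for built, streamed in zip(stack.adjacencies,
                                   iter_stack(net96.matrix, stack.grid)):
            np.testing.assert_array_equal(built, streamed)

    def test_tie_break_deterministic(self):
        m = np.zeros((5, 5))
        # four ties at 0.5 spanning the cut, distinguished only by (i, j)
        for i, j in [(0, 1), (0, 2), (1, 3), (2, 4)]:
            m[i, j] = m[j, i] = 0.5
        m[3, 4] = m[4, 3] = 0.9
        net = net_from_matrix(m)
        adj = threshold_sparsity(net, 0.3)  # k = 3 of 10 edges
        assert int(adj.sum()) // 2 == 3
        assert adj[3, 4]
        assert adj[0, 1] and adj[0, 2]  # lexicographically first ties win
        np.testing.assert_array_equal(adj, threshold_sparsity(net, 0.3))

    def test_absolute_ranking_switch(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = -0.95
        m[2, 3] = m[3, 2] = 0.4
        m[0, 2] = m[2, 0] = 0.1
        net = net_from_matrix(m)
        signed = threshold_sparsity(net, 1 / 6)  # keep 1 edge
        absolute = threshold_sparsity(net, 1 / 6, ranking="absolute")
        assert signed[2, 3] and not signed[0, 1]
        assert absolute[0, 1] and not absolute[2, 3]

    def test_invalid_sparsity(self, net96):
        with pytest.raises(ValueError):
            threshold_sparsity(net96, 0.0)


class TestSparsityGrid:
    def test_default_grid(self):
        g = default_grid()
        assert len(g) == 46
        assert g.values[0] == 0.05 and g.values[-1] == 0.50
        assert np.allclose(np.diff(g.as_array()), 0.01)

    @pytest.mark.parametrize("values", [(0.5, 0.4), (0.0, 0.1), (0.2, 0.2)])
    def test_invalid_grids_rejected(self, values):
        with pytest.raises(ValueError):
            SparsityGrid(values)


class TestMinDensityConnected:
    def test_dominant_spanning_tree(self):
        # weights make a star on node 0 strictly dominate everything else
        m = np.full((5, 5), 0.1)
        np.fill_diagonal(m, 0.0)
        for j in range(1, 5):
            m[0, j] = m[j, 0] = 0.9 - 0.01 * j
        net = net_from_matrix(m)
        density, adj = min_density_connected(net)
        assert density == pytest.approx(4 / 10)
        expected = np.zeros((5, 5), dtype=bool)
        expected[0, 1:] = expected[1:, 0] = True
        np.testing.assert_array_equal(adj, expected)

    def test_two_active_nodes(self, net96):
        density, adj = min_density_connected(net96, active_nodes=[3, 17])
        assert density == 1.0
        assert adj.sum() == 2

    def test_minimality_matches_oracle_and_connected(self):
        from scipy.sparse.csgraph import connected_components
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(5, 12))
            w = rng.normal(size=(n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            w = np.clip(w, -0.99, 0.99)
            net = net_from_matrix(w)
            density, adj = min_density_connected(net)
            ncomp, _ = connected_components(adj.astype(np.int8), directed=False)
            assert ncomp == 1
            k_oracle = oracle_min_density_k(w)
            assert int(adj.sum()) // 2 == k_oracle
            assert density == pytest.approx(k_oracle / (n * (n - 1) / 2))

    def test_too_few_active_nodes(self, net96):
        with pytest.raises(ValueError):
            min_density_connected(net96, active_nodes=[5])


class TestRankedEdges:
    def test_signed_descending_with_tiebreaks(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 0.5
        m[2, 3] = m[3, 2] = 0.5
        m[0, 3] = m[3, 0] = -0.8
        i, j, w = ranked_edges(m)
        assert (np.diff(w) <= 1e-15).all()
        # tie at 0.5: (0,1) precedes (2,3); most negative last
        assert (i[0], j[0]) == (0, 1) and (i[1], j[1]) == (2, 3)
        assert w[-1] == -0.8
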