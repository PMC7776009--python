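"""Thresholding, weighted graph metrics, null ensembles and AUC curves."""

import numpy as np
import networkx as nx
import pytest

from conftest import (
    oracle_betweenness,
    oracle_clustering,
    oracle_distances,
    oracle_global_efficiency,
    oracle_local_efficiency,
    random_weighted_graph,
)
from morphnet import (
    SparsityGrid,
    ThresholdedGraph,
    global_metrics,
    metric_auc_curve,
    nodal_metrics,
    random_null_ensemble,
    small_world_indices,
    threshold_by_sparsity,
    toy_graph,
)
from morphnet.metrics import AUCRecord, EmptyGraphError, GraphMetricError, RewireError


def as_graph(adj, s=0.5):
    return ThresholdedGraph(adjacency=np.asarray(adj, float), sparsity=s)


class TestThresholding:
    def test_edge_count_rule_for_90_regions(self):
        rng = np.random.default_rng(0)
        m = rng.random((90, 90))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        g = threshold_by_sparsity(m, 0.10)
        assert g.n_edges == 400  # floor(0.10 * 4005)

    def test_k4_top_edges_match_exhaustive_sort(self):
        m = np.eye(4)
        weights = {(0, 1): 0.9, (0, 2): 0.2, (0, 3): 0.7,
                   (1, 2): 0.5, (1, 3): 0.4, (2, 3): 0.8}
        for (i, j), w in weights.items():
            m[i, j] = m[j, i] = w
        g = threshold_by_sparsity(m, 0.5)  # floor(3)
        kept = {(i, j) for i, j in zip(*np.nonzero(np.triu(g.adjacency)))}
        expected = set(sorted(weights, key=weights.get, reverse=True)[:3])
        assert kept == expected

    def test_nestedness_and_eglob_monotone(self):
        rng = np.random.default_rng(5)
        m = rng.random((20, 20))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        prev_edges, prev_eglob = set(), 0.0
        for s in [0.1, 0.15, 0.2, 0.3, 0.5]:
            g = threshold_by_sparsity(m, s)
            edges = {(i, j) for i, j in zip(*np.nonzero(np.triu(g.adjacency)))}
            assert prev_edges <= edges
            eglob = global_metrics(g).eglob
            assert eglob >= prev_eglob - 1e-12
            prev_edges, prev_eglob = edges, eglob

    def test_tie_break_is_lexicographic(self):
        m = np.ones((4, 4))  # all off-diagonal weights tie
        g = threshold_by_sparsity(m, 0.34)  # floor(0.34*6) = 2 edges
        kept = sorted((i, j) for i, j in zip(*np.nonzero(np.triu(g.adjacency))))
        assert kept == [(0, 1), (0, 2)]

    def test_empty_graph_error(self):
        with pytest.raises(EmptyGraphError):
            threshold_by_sparsity(np.ones((4, 4)), 0.05)


class TestGlobalMetrics:
    def test_complete_k4(self):
        gm = global_metrics(as_graph(toy_graph("complete", 4)))
        assert gm.cp == pytest.approx(1.0)
        assert gm.eglob == pytest.approx(1.0)
        assert gm.lp == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        gm = global_metrics(as_graph(toy_graph("star", 4)))
        assert gm.cp == 0.0
        assert gm.eloc == 0.0

    def test_path3_distances(self):
        d = oracle_distances(toy_graph("path", 3))
        assert sorted([d[0, 1], d[1, 2], d[0, 2]]) == [1.0, 1.0, 2.0]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_graph_matches_bruteforce_oracle(self, seed):
        adj = random_weighted_graph(10, 0.4, seed)
        gm = global_metrics(as_graph(adj))
        assert gm.cp == pytest.approx(oracle_clustering(adj).mean(), rel=1e-9)
        assert gm.eglob == pytest.approx(oracle_global_efficiency(adj), rel=1e-9)
        assert gm.lp == pytest.approx(1.0 / oracle_global_efficiency(adj), rel=1e-9)
        assert gm.eloc == pytest.approx(oracle_local_efficiency(adj), rel=1e-9)

    def test_clustering_matches_networkx_onnela(self):
        adj = random_weighted_graph(12, 0.5, 9)
        g = nx.from_numpy_array(adj)
        expected = np.mean(list(nx.clustering(g, weight="weight").values()))
        assert global_metrics(as_graph(adj)).cp == pytest.approx(expected, rel=1e-9)

    def test_no_edges_error(self):
        with pytest.raises(EmptyGraphError):
            global_metrics(as_graph(np.zeros((3, 3))))


class TestNodalMetrics:
    def test_star_center_and_leaf(self):
        nm = nodal_metrics(as_graph(toy_graph("star", 4)))
        assert nm.degree[0] == 3
        assert nm.efficiency[0] == pytest.approx(1.0)
        assert nm.betweenness[0] == pytest.approx(3.0)
        assert nm.degree[1] == 1
        assert nm.efficiency[1] == pytest.approx(2 / 3)
        assert nm.betweenness[1] == 0.0

    @pytest.mark.parametrize("seed", [4, 8])
    def test_betweenness_matches_exhaustive_enumeration(self, seed):
        adj = random_weighted_graph(8, 0.4, seed)
        nm = nodal_metrics(as_graph(adj))
        assert np.allclose(nm.betweenness, oracle_betweenness(adj), atol=1e-9)

    def test_efficiency_matches_oracle(self):
        adj = random_weighted_graph(9, 0.5, 6)
        nm = nodal_metrics(as_graph(adj))
        d = oracle_distances(adj)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1 / d, 0.0)
        assert np.allclose(nm.efficiency, inv.sum(1) / 8, atol=1e-9)

    def test_weight_degree_mode(self):
        adj = toy_graph("weighted_fixture", 5)
        nm = nodal_metrics(as_graph(adj), degree_mode="weight")
        assert np.allclose(nm.degree, adj.sum(1))
        with pytest.raises(GraphMetricError):
            nodal_metrics(as_graph(adj), degree_mode="bogus")


class TestNullEnsemble:
    def test_degree_sequence_preserved_and_reproducible(self):
        adj = random_weighted_graph(12, 0.4, 3)
        g = as_graph(adj)
        nulls = random_null_ensemble(g, 20, seed=42)
        assert len(nulls) == 20
        deg = np.sort((adj > 0).sum(1))
        for n in nulls:
            assert np.array_equal(np.sort((n.adjacency > 0).sum(1)), deg)
            # weight multiset preserved
            assert np.allclose(
                np.sort(n.adjacency[np.triu_indices(12, 1)]),
                np.sort(adj[np.triu_indices(12, 1)]),
            )
        again = random_null_ensemble(g, 20, seed=42)
        assert all(
            np.array_equal(a.adjacency, b.adjacency)
            for a, b in zip(nulls, again)
        )

    def test_lattice_clustering_exceeds_null_mean(self):
        lattice = nx.to_numpy_array(nx.watts_strogatz_graph(10, 4, 0.0))
        g = as_graph(lattice)
        nulls = random_null_ensemble(g, 50, seed=1)
        cp = global_metrics(g).cp
        null_cp = np.mean([global_metrics(n).cp for n in nulls])
        assert null_cp < cp

    def test_too_few_edges(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        with pytest.raises(RewireError):
            random_null_ensemble(as_graph(adj), 5, seed=0)


class TestSmallWorld:
    def test_self_ensemble_normalises_to_one(self):
        g = as_graph(random_weighted_graph(10, 0.5, 2))
        gamma, lam, sigma = small_world_indices(g, [g, g, g])
        assert gamma == pytest.approx(1.0)
        assert lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_sigma_is_gamma_over_lambda(self):
        g = as_graph(random_weighted_graph(12, 0.4, 7))
        nulls = random_null_ensemble(g, 10, seed=3)
        gamma, lam, sigma = small_world_indices(g, nulls)
        assert sigma == pytest.approx(gamma / lam, abs=1e-9)

    def test_watts_strogatz_regime(self):
        """A slightly rewired ring lattice is small-world: gamma >> 1,
        lambda near 1."""
        ws = nx.to_numpy_array(nx.watts_strogatz_graph(30, 6, 0.15, seed=0))
        g = as_graph(ws)
        nulls = random_null_ensemble(g, 50, seed=9)
        gamma, lam, sigma = small_world_indices(g, nulls)
        assert gamma > 1.5
        assert abs(lam - 1.0) < 0.3
        assert sigma > 1.0


class TestAUC:
    def test_default_grid_has_25_inclusive_thresholds(self):
        grid = SparsityGrid.from_range()
        assert len(grid) == 25
        assert grid.values[0] == pytest.approx(0.10)
        assert grid.values[-1] == pytest.approx(0.34)

    def test_constant_curve_auc(self):
        grid = SparsityGrid.from_range()
        rec = AUCRecord("const", grid.as_array(), np.full(25, 3.0))
        assert rec.auc == pytest.approx(0.24 * 3.0)

    def test_linear_curve_closed_form(self):
        t = SparsityGrid.from_range().as_array()
        values = 2.0 * t + 1.0  # trapezoid is exact on linear curves
        rec = AUCRecord("lin", t, values)
        width = t[-1] - t[0]
        assert rec.auc == pytest.approx((values[0] + values[-1]) / 2 * width)

    def test_curves_over_grid(self):
        rng = np.random.default_rng(12)
        m = rng.random((15, 15))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        grid = SparsityGrid.from_range(0.15, 0.35, 0.1)
        records = metric_auc_curve(m, grid, n_rand=5, seed=4)
        assert records["cp"].values.shape == (3,)
        assert records["degree"].values.shape == (3, 15)
        assert records["degree"].auc.shape == (15,)
        # AUC equals the trapezoid of the stored curve
        assert records["eglob"].auc == pytest.approx(
            np.trapezoid(records["eglob"].values, grid.as_array())
        )
        # deterministic under the same seed
        again = metric_auc_curve(m, grid, n_rand=5, seed=4)
        assert np.allclose(records["gamma"].values, again["gamma"].values)
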