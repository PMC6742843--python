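"""Graph construction and the seven node metrics, checked against
analytic values, a brute-force enumeration oracle, and networkx."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roinet import (
    ConnectivityMatrix,
    GraphConfig,
    SubjectGraph,
    node_centralities,
    node_integration,
    node_metrics,
    node_segregation,
    shortest_path_stats,
    threshold_binarize,
)

from oracles import brute_metrics, brute_sigma


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return SubjectGraph(a, roi_labels=[f"n{i}" for i in range(n)])


def zmat(values, kind="FUN"):
    v = np.asarray(values, dtype=float)
    np.fill_diagonal(v, np.nan)
    return ConnectivityMatrix(v, kind=kind,
                              roi_labels=[f"n{i}" for i in range(len(v))])


K4 = graph_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
STAR4 = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])  # node 0 is the hub
PATH3 = graph_from_edges(3, [(0, 1), (1, 2)])
CYCLE5 = graph_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])


class TestThresholdBinarize:
    def test_absolute_threshold_both_signs(self):
        z = zmat([[0, 0.5, -0.45], [0.5, 0, 0.1], [-0.45, 0.1, 0]])
        g = threshold_binarize(z, GraphConfig(threshold=0.4))
        assert g.adjacency[0, 1] == 1  # 0.5 > 0.4
        assert g.adjacency[0, 2] == 1  # |-0.45| > 0.4
        assert g.adjacency[1, 2] == 0  # 0.1 below threshold

    def test_boundary_value_excluded(self):
        z = zmat([[0, 0.4], [0.4, 0]])
        g = threshold_binarize(z, GraphConfig(threshold=0.4))
        assert g.n_edges == 0

    def test_anticorrelation_equivalent_to_correlation(self):
        zp = zmat([[0, 0.45], [0.45, 0]])
        zn = zmat([[0, -0.45], [-0.45, 0]])
        assert np.array_equal(
            threshold_binarize(zp).adjacency, threshold_binarize(zn).adjacency
        )

    def test_eff_or_symmetrization(self):
        v = np.array([[np.nan, 0.6], [0.1, np.nan]])
        z = ConnectivityMatrix(v, kind="EFF", roi_labels=["a", "b"], is_z=True)
        g = threshold_binarize(z, GraphConfig(threshold=0.4))
        assert g.adjacency[0, 1] == 1

    def test_eff_and_symmetrization(self):
        v = np.array([[np.nan, 0.6], [0.1, np.nan]])
        z = ConnectivityMatrix(v, kind="EFF", roi_labels=["a", "b"], is_z=True)
        g = threshold_binarize(z, GraphConfig(threshold=0.4, eff_symmetrization="AND"))
        assert g.n_edges == 0

    def test_nan_never_makes_an_edge(self):
        v = np.full((3, 3), np.nan)
        z = ConnectivityMatrix(v, kind="FUN", roi_labels=list("abc"), is_z=True)
        assert threshold_binarize(z).n_edges == 0


class TestShortestPaths:
    def test_complete_graph(self):
        d, sigma = shortest_path_stats(K4)
        off = ~np.eye(4, dtype=bool)
        assert np.all(d[off] == 1)
        assert np.all(sigma[off] == 1)

    def test_path_graph(self):
        d, sigma = shortest_path_stats(PATH3)
        assert d[0, 2] == 2
        assert sigma[0, 2] == 1

    def test_four_cycle_has_two_geodesics(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        d, sigma = shortest_path_stats(g)
        assert d[0, 2] == 2
        assert sigma[0, 2] == 2

    def test_disconnected_distance_infinite(self):
        g = graph_from_edges(3, [(0, 1)])
        d, _ = shortest_path_stats(g)
        assert np.isinf(d[0, 2])

    def test_sigma_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 8))
            a = (rng.random((n, n)) < 0.4).astype(int)
            a = np.triu(a, 1)
            a = a + a.T
            g = SubjectGraph(a, roi_labels=[f"n{i}" for i in range(n)])
            _, sigma = shortest_path_stats(g)
            assert np.allclose(sigma, brute_sigma(a))


class TestCentrality:
    def test_star_center_and_leaves(self):
        k, cost, bc = node_centralities(STAR4)
        assert k[0] == 3 and cost[0] == pytest.approx(1.0)
        assert bc[0] == pytest.approx(1.0)  # all 3 leaf pairs route via hub
        assert np.all(k[1:] == 1)
        assert np.allclose(cost[1:], 1 / 3)
        assert np.allclose(bc[1:], 0.0)

    def test_complete_graph_zero_betweenness(self):
        _, _, bc = node_centralities(K4)
        assert np.allclose(bc, 0.0)

    def test_five_cycle_betweenness(self):
        _, _, bc = node_centralities(CYCLE5)
        assert np.allclose(bc, 1 / 6)  # 1 of 6 pair-geodesics per node

    def test_raw_normalization_option(self):
        _, _, raw = node_centralities(STAR4, GraphConfig(betweenness_normalization="raw"))
        assert raw[0] == pytest.approx(3.0)

    def test_two_node_graph_betweenness_zero(self):
        g = graph_from_edges(2, [(0, 1)])
        _, _, bc = node_centralities(g)
        assert np.all(bc == 0)


class TestIntegration:
    def test_complete_graph(self):
        length, eglob = node_integration(K4)
        assert np.allclose(length, 1.0)
        assert np.allclose(eglob, 1.0)

    def test_star_leaf(self):
        length, eglob = node_integration(STAR4)
        assert length[1] == pytest.approx(5 / 3)   # (1 + 2 + 2) / 3
        assert eglob[1] == pytest.approx(2 / 3)    # (1 + .5 + .5) / 3

    def test_isolated_node_conventions(self):
        g = graph_from_edges(3, [(0, 1)])
        length, eglob = node_integration(g)
        assert np.isnan(length[2])
        assert eglob[2] == 0.0
        assert length[0] == pytest.approx(1.0)  # only reachable node counts
        assert eglob[0] == pytest.approx(0.5)   # (1 + 0) / 2


class TestSegregation:
    def test_complete_graph(self):
        c, eloc = node_segregation(K4)
        assert np.allclose(c, 1.0)
        assert np.allclose(eloc, 1.0)  # neighbour subgraph is K3

    def test_star_center_unclustered(self):
        c, eloc = node_segregation(STAR4)
        assert c[0] == 0.0 and eloc[0] == 0.0
        assert np.all(c[1:] == 0.0)  # leaves have a single neighbour

    def test_triangle_with_pendant(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
        c, _ = node_segregation(g)
        assert c[0] == pytest.approx(1 / 3)  # 1 edge among 3 neighbours
        assert c[1] == pytest.approx(1.0)


def _random_graph(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    a = nx.to_numpy_array(g, dtype=int)
    return SubjectGraph(a, roi_labels=[f"n{i}" for i in range(n)])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_metrics_match_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        g = _random_graph(n, float(rng.uniform(0.2, 0.8)), seed)
        ours = node_metrics(g)
        ref = brute_metrics(g.adjacency)
        for col in ours.columns:
            np.testing.assert_allclose(
                ours[col].to_numpy(), ref[col], atol=1e-10, err_msg=col
            )

    @pytest.mark.parametrize("seed", range(15))
    def test_metrics_match_networkx(self, seed):
        """Independent library cross-check on connected random graphs."""
        g = _random_graph(7, 0.5, seed=100 + seed)
        gx = nx.from_numpy_array(g.adjacency)
        ours = node_metrics(g)
        _, _, bc = node_centralities(g)
        ref_bc = nx.betweenness_centrality(gx, normalized=True)
        np.testing.assert_allclose(bc, [ref_bc[i] for i in range(7)], atol=1e-10)
        ref_c = nx.clustering(gx)
        np.testing.assert_allclose(
            ours["clustering"], [ref_c[i] for i in range(7)], atol=1e-10
        )
        if nx.is_connected(gx):
            spl = dict(nx.all_pairs_shortest_path_length(gx))
            ref_l = [np.mean([spl[i][j] for j in range(7) if j != i]) for i in range(7)]
            np.testing.assert_allclose(ours["avg_path_length"], ref_l, atol=1e-10)
            ref_eg = [
                np.mean([1 / spl[i][j] for j in range(7) if j != i]) for i in range(7)
            ]
            np.testing.assert_allclose(ours["global_efficiency"], ref_eg, atol=1e-10)


@st.composite
def adjacency(draw):
    n = draw(st.integers(min_value=2, max_value=9))
    bits = draw(st.lists(st.booleans(), min_size=n * (n - 1) // 2,
                         max_size=n * (n - 1) // 2))
    a = np.zeros((n, n), dtype=int)
    a[np.triu_indices(n, 1)] = np.asarray(bits, dtype=int)
    return a + a.T


class TestMetricProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(adjacency())
    def test_metric_bounds(self, a):
        n = a.shape[0]
        g = SubjectGraph(a, roi_labels=[f"n{i}" for i in range(n)])
        m = node_metrics(g)
        assert np.all(m["degree"] >= 0)
        assert np.all(m["degree"] == m["degree"].astype(int))
        for col in ("cost", "betweenness", "global_efficiency",
                    "local_efficiency", "clustering"):
            assert np.all((m[col] >= 0) & (m[col] <= 1)), col
        length = m["avg_path_length"]
        defined = length.notna()
        assert np.all(length[defined] >= 1)
        assert defined.to_numpy().tolist() == (m["degree"] > 0).tolist()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(adjacency(), st.randoms(use_true_random=False))
    def test_adding_edge_never_decreases_degree_cost_eglob(self, a, rnd):
        n = a.shape[0]
        absent = [(i, j) for i in range(n) for j in range(i + 1, n) if not a[i, j]]
        if not absent:
            return
        i, j = absent[rnd.randrange(len(absent))]
        g0 = SubjectGraph(a, roi_labels=[f"n{k}" for k in range(n)])
        a2 = a.copy()
        a2[i, j] = a2[j, i] = 1
        g1 = SubjectGraph(a2, roi_labels=[f"n{k}" for k in range(n)])
        m0, m1 = node_metrics(g0), node_metrics(g1)
        for col in ("degree", "cost", "global_efficiency"):
            assert np.all(m1[col].to_numpy() >= m0[col].to_numpy() - 1e-12), col
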