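import math

import networkx as nx
import numpy as np
import pytest

from coexnet.association import AssociationMatrix
from coexnet.network import (
    DEFAULT_THRESHOLD_GRID,
    DegenerateMetricError,
    Network,
    SelectionCriteria,
    ThresholdMetrics,
    coverage_stats,
    degree_distribution_fit,
    mean_clustering,
    mean_path_length,
    metrics_table,
    refine_thresholds,
    select_threshold,
    threshold_adjacency,
)
from coexnet.simulate import generate_benchmark_graph

from oracles import (
    clustering_by_triangles,
    floyd_warshall_mean_path,
    ols_loglog,
    union_find_components,
)


def _am(ids, pairs):
    n = len(ids)
    rho = np.eye(n)
    for (i, j), v in pairs.items():
        rho[i, j] = rho[j, i] = v
    return AssociationMatrix(tuple(ids), rho)


def _net_from_graph(g):
    return Network(g, tuple(str(n) for n in g.nodes), None)


class TestThresholdAdjacency:
    def test_unachievable_threshold_gives_empty_graph(self):
        am = _am("abc", {(0, 1): 0.9, (0, 2): 0.5, (1, 2): -0.95})
        net = threshold_adjacency(am, 1.0)
        assert net.n_edges == 0

    def test_absolute_value_rule(self):
        am = _am("abc", {(0, 1): 0.9, (0, 2): 0.5, (1, 2): -0.95})
        net = threshold_adjacency(am, 0.855)
        assert {frozenset(e) for e in net.graph.edges} == {
            frozenset("ab"), frozenset("bc")}

    def test_positive_mode_drops_negative_correlations(self):
        am = _am("abc", {(0, 1): 0.9, (0, 2): 0.5, (1, 2): -0.95})
        net = threshold_adjacency(am, 0.855, mode="positive")
        assert {frozenset(e) for e in net.graph.edges} == {frozenset("ab")}

    def test_vanishing_threshold_gives_complete_graph(self):
        rng = np.random.default_rng(1)
        n = 10
        rho = np.corrcoef(rng.normal(size=(n, 30)))
        am = AssociationMatrix(tuple(f"g{i}" for i in range(n)), rho)
        net = threshold_adjacency(am, 1e-12)
        assert net.n_edges == n * (n - 1) // 2

    def test_edges_nested_under_increasing_threshold(self):
        rng = np.random.default_rng(2)
        rho = np.corrcoef(rng.normal(size=(20, 8)))
        am = AssociationMatrix(tuple(f"g{i}" for i in range(20)), rho)
        prev = None
        for t in (0.2, 0.4, 0.6, 0.8):
            edges = {frozenset(e) for e in threshold_adjacency(am, t).graph.edges}
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestDegreeFit:
    def test_exact_power_law(self):
        # disjoint pieces realizing the histogram n(k) = 64/k, k in {1,2,4,8}:
        # 8 stars K1,8 (8 centers deg 8, 64 leaves deg 1), 4 cycles C8
        # (32 nodes deg 2), one circulant C16(1,2) (16 nodes deg 4)
        g = nx.Graph()
        for s in range(8):
            g = nx.disjoint_union(g, nx.star_graph(8))
        for c in range(4):
            g = nx.disjoint_union(g, nx.cycle_graph(8))
        g = nx.disjoint_union(g, nx.circulant_graph(16, [1, 2]))
        degs = [d for _, d in g.degree()]
        assert {k: degs.count(k) for k in sorted(set(degs))} == {
            1: 64, 2: 32, 4: 16, 8: 8}
        slope, r2 = degree_distribution_fit(_net_from_graph(g))
        assert slope == pytest.approx(-1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_point_histogram_fits_perfectly(self):
        # path of 3 nodes: degrees {1: 2, 2: 1}
        net = generate_benchmark_graph("path", {"n": 3})
        _, r2 = degree_distribution_fit(net)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_ols_on_preferential_attachment(self):
        net = generate_benchmark_graph("preferential_attachment",
                                       {"n": 200, "m": 2}, rng_seed=3)
        slope, r2 = degree_distribution_fit(net)
        degs = [d for _, d in net.graph.degree() if d >= 1]
        ks, counts = np.unique(degs, return_counts=True)
        oslope, or2 = ols_loglog(ks, counts)
        assert slope == pytest.approx(oslope, abs=1e-10)
        assert r2 == pytest.approx(or2, abs=1e-10)

    def test_single_degree_is_degenerate(self):
        net = generate_benchmark_graph("cycle", {"n": 6})  # all degree 2
        with pytest.raises(DegenerateMetricError):
            degree_distribution_fit(net)


class TestClusteringAndPaths:
    def test_triangle(self):
        net = generate_benchmark_graph("clique", {"n": 3})
        assert mean_clustering(net) == pytest.approx(1.0)
        assert mean_path_length(net) == pytest.approx(1.0)

    def test_path_has_no_triangles(self):
        net = generate_benchmark_graph("path", {"n": 3})
        assert mean_clustering(net) == 0.0
        assert mean_path_length(net) == pytest.approx(4 / 3)

    def test_chorded_square_against_triangle_oracle(self):
        g = nx.cycle_graph(4)
        g.add_edge(0, 2)
        expected = clustering_by_triangles(g)  # {2/3, 1, 2/3, 1} -> 5/6
        assert expected == pytest.approx(5 / 6)
        assert mean_clustering(_net_from_graph(g)) == pytest.approx(
            expected, abs=1e-12)

    def test_random_graph_against_floyd_warshall(self):
        g = nx.gnp_random_graph(50, 0.1, seed=9)
        got = mean_path_length(_net_from_graph(g))
        assert got == pytest.approx(floyd_warshall_mean_path(g), abs=1e-12)

    def test_empty_graph_degenerate(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        with pytest.raises(DegenerateMetricError):
            mean_path_length(_net_from_graph(g))


class TestCoverage:
    def test_fully_connected_uses_everything(self):
        net = generate_benchmark_graph("clique", {"n": 5})
        assert coverage_stats(net) == (100.0, 100.0)

    def test_two_components_and_isolates(self):
        g = nx.Graph()
        g.add_edges_from([(i, i + 1) for i in range(5)])  # 6-vertex path
        g.add_edge(10, 11)                                # 2-vertex component
        net = Network(g, tuple(str(i) for i in range(10)), None)
        pct_used, pct_big = coverage_stats(net, total_genes=10)
        assert pct_used == pytest.approx(80.0)
        assert pct_big == pytest.approx(75.0)

    def test_single_edge_among_many_genes(self):
        g = nx.Graph([("a", "b")])
        net = Network(g, tuple(f"g{i}" for i in range(100)), None)
        assert coverage_stats(net, 100) == (2.0, 100.0)

    def test_mean_degree_identity(self):
        # mean degree over used vertices is always 2E/|used|
        for seed in range(5):
            g = nx.gnp_random_graph(30, 0.15, seed=seed)
            net = _net_from_graph(g)
            used = net.used_vertices
            if not used:
                continue
            mean_deg = np.mean([g.degree(v) for v in used])
            assert mean_deg == pytest.approx(2 * net.n_edges / len(used))


class TestRefineAndSelect:
    def _random_am(self, seed, n=40, s=10):
        rng = np.random.default_rng(seed)
        rho = np.corrcoef(rng.normal(size=(n, s)))
        return AssociationMatrix(tuple(f"g{i}" for i in range(n)), rho)

    def test_pct_used_and_edges_non_increasing(self):
        am = self._random_am(31)
        rows = refine_thresholds(am, [0.3, 0.5, 0.7, 0.9])
        for a, b in zip(rows, rows[1:]):
            assert b.n_edges <= a.n_edges
            assert b.pct_used <= a.pct_used

    def test_degenerate_row_reported_not_raised(self):
        am = self._random_am(32, n=10, s=50)  # near-zero correlations
        rows = refine_thresholds(am, [1.0])
        assert rows[0].pct_used == 0.0
        assert math.isnan(rows[0].r2)

    def test_default_grid_is_refinement_range(self):
        assert DEFAULT_THRESHOLD_GRID == (0.845, 0.85, 0.855, 0.858, 0.86,
                                          0.862)

    def test_non_increasing_grid_rejected(self):
        am = self._random_am(33)
        with pytest.raises(ValueError):
            refine_thresholds(am, [0.5, 0.5])

    def test_single_passing_row_returned_unmarked(self):
        row = ThresholdMetrics(0.85, r2=0.95, slope=-1.2, mean_cc=0.4,
                               mean_path=4.0, pct_used=97.0, pct_big_comp=99.0)
        res = select_threshold([row])
        assert not res.relaxed and res.metrics is row

    def test_higher_r2_wins_among_passing_rows(self):
        mk = lambda t, r2: ThresholdMetrics(t, r2, -1.2, 0.4, 4.0, 97.0, 99.0)
        res = select_threshold([mk(0.85, 0.92), mk(0.86, 0.93)])
        assert res.metrics.threshold == 0.86

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            select_threshold([])

    # the published refinement table for the shoot/inflorescence network
    _PUBLISHED_ROWS = [
        ThresholdMetrics(0.862, 0.82, -1.3305, 0.4069, 4.3394, 95.7515, 99.3275),
        ThresholdMetrics(0.860, 0.82, -1.2965, 0.4099, 4.2793, 95.9714, 99.4027),
        ThresholdMetrics(0.858, 0.81, -1.2914, 0.4123, 4.2296, 96.1992, 99.4367),
        ThresholdMetrics(0.855, 0.81, -1.2877, 0.4146, 4.1603, 96.5133, 99.4060),
        ThresholdMetrics(0.850, 0.80, -1.2481, 0.4184, 4.0528, 96.9609, 99.4898),
        ThresholdMetrics(0.845, 0.79, -1.2125, 0.4220, 3.9596, 97.4242, 99.6292),
    ]

    def test_published_table_fails_r2_bound_and_relaxes(self):
        # no row reaches r2 > 0.9, so selection is relaxed; every row passes
        # the four topology bounds, the highest r2 (0.82) is shared by 0.86
        # and 0.862, and the tie-break toward the larger threshold picks
        # 0.862
        res = select_threshold(self._PUBLISHED_ROWS)
        assert res.relaxed
        assert res.n_satisfied == 4
        assert res.metrics.threshold == 0.862

    def test_published_best_row_selectable_under_custom_criteria(self):
        # with bounds set to the operating point actually reported
        # (r2 > 0.80, %used > 96.3) the 0.855 row is the unique full pass
        crit = SelectionCriteria(r2_min=0.80, pct_used_min=96.3)
        res = select_threshold(self._PUBLISHED_ROWS, crit)
        assert not res.relaxed
        assert res.metrics.threshold == 0.855

    def test_metrics_table_column_order(self):
        df = metrics_table(self._PUBLISHED_ROWS)
        assert list(df.columns) == ["threshold", "R2", "slope", "meanCC",
                                    "meanPath", "pct_used", "pct_bigComp"]
        assert df["threshold"].iloc[0] == 0.862
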