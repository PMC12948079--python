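import math

import networkx as nx
import numpy as np
import pytest

import phytorank as pr
from phytorank import ConfigurationError
from tests import oracle
from tests.conftest import random_small_graphs

PATH3 = nx.path_graph(["a", "b", "c"])
C4 = nx.cycle_graph(4)
C5 = nx.cycle_graph(5)
K4 = nx.complete_graph(4)
STAR3 = nx.star_graph(3)  # node 0 is the center
TWO_EDGES = nx.Graph([("a", "b"), ("c", "d")])
WITH_ISOLATE = nx.Graph()
WITH_ISOLATE.add_edge("a", "b")
WITH_ISOLATE.add_node("z")


class TestSpecificValues:
    """Hand-derived scores on tiny named graphs."""

    @pytest.mark.parametrize("graph,expected", [
        (PATH3, {"a": 1, "b": 2, "c": 1}),
        (STAR3, {0: 3, 1: 1, 2: 1, 3: 1}),
        (WITH_ISOLATE, {"a": 1, "b": 1, "z": 0}),
    ])
    def test_degree(self, graph, expected):
        assert pr.degree_scores(graph) == expected

    @pytest.mark.parametrize("graph,expected", [
        (PATH3, {"a": 0.0, "b": 1.0, "c": 0.0}),
        (STAR3, {0: 3.0, 1: 0.0, 2: 0.0, 3: 0.0}),
        (C4, {0: 0.5, 1: 0.5, 2: 0.5, 3: 0.5}),  # two geodesics per opposite pair
    ])
    def test_betweenness(self, graph, expected):
        scores = pr.betweenness_scores(graph)
        assert scores == pytest.approx(expected)

    @pytest.mark.parametrize("graph,expected", [
        (PATH3, {"a": 1.5, "b": 2.0, "c": 1.5}),
        (TWO_EDGES, {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}),
        (K4, {0: 3.0, 1: 3.0, 2: 3.0, 3: 3.0}),
    ])
    def test_harmonic_closeness(self, graph, expected):
        assert pr.closeness_scores(graph) == pytest.approx(expected)

    @pytest.mark.parametrize("graph,expected", [
        (PATH3, {"a": 2, "b": 1, "c": 2}),
        (C5, {i: 2 for i in range(5)}),
        (WITH_ISOLATE, {"a": 1, "b": 1, "z": 0}),
    ])
    def test_eccentricity(self, graph, expected):
        assert pr.eccentricity_scores(graph) == expected

    @pytest.mark.parametrize("graph,expected", [
        (PATH3, {"a": 1.5, "b": 2.0, "c": 1.5}),
        (nx.complete_graph(3), {0: 1.0, 1: 1.0, 2: 1.0}),
        (STAR3, {0: 2.0, 1: 4 / 3, 2: 4 / 3, 3: 4 / 3}),
    ])
    def test_radiality(self, graph, expected):
        assert pr.radiality_scores(graph) == pytest.approx(expected)

    @pytest.mark.parametrize("graph,expected", [
        (PATH3, {"a": 0, "b": 1, "c": 0}),
        (STAR3, {0: 3, 1: 0, 2: 0, 3: 0}),
        (C4, {i: 1 for i in range(4)}),  # one of two geodesics crosses each node
    ])
    def test_stress(self, graph, expected):
        assert pr.stress_scores(graph) == expected

    @pytest.mark.parametrize("graph,expected", [
        (STAR3, {0: 3, 1: 0, 2: 0, 3: 0}),
        (PATH3, {"a": 2, "b": 2, "c": 2}),  # threshold 3/4: every n_s(v) = 1 or 2 counts
        (WITH_ISOLATE, {"a": 1, "b": 1, "z": 0}),
    ])
    def test_bottleneck(self, graph, expected):
        assert pr.bottleneck_scores(graph) == expected


class TestShortestPathStructure:
    def test_path_graph(self):
        sps = pr.shortest_path_structure(PATH3)
        assert sps.dist("a", "c") == 2
        assert sps.sigma("a", "c") == 1
        assert sps.predecessors("a")["c"] == {"b"}
        assert sps.dist("b", "b") == 0
        assert sps.sigma("b", "b") == 1

    def test_cycle_has_two_geodesics_across(self):
        sps = pr.shortest_path_structure(C4)
        assert sps.dist(0, 2) == 2
        assert sps.sigma(0, 2) == 2
        assert sps.predecessors(0)[2] == {1, 3}

    def test_unreachable_pairs_flagged(self):
        sps = pr.shortest_path_structure(TWO_EDGES)
        assert math.isinf(sps.dist("a", "c"))
        assert sps.dist("a", "c") == pr.UNREACHABLE
        assert sps.sigma("a", "c") == 0


ORACLE_SUITE = random_small_graphs(30, base_seed=77)


@pytest.mark.parametrize("name,graph", ORACLE_SUITE, ids=[n for n, _ in ORACLE_SUITE])
def test_all_exact_measures_match_bruteforce(name, graph):
    """Engine output equals explicit path enumeration on random small graphs."""
    bet, stress = oracle.betweenness_and_stress(graph)
    checks = [
        (pr.degree_scores(graph), oracle.degree(graph), 0),
        (pr.betweenness_scores(graph), bet, 1e-9),
        (pr.stress_scores(graph), stress, 0),
        (pr.closeness_scores(graph), oracle.harmonic_closeness(graph), 1e-9),
        (pr.eccentricity_scores(graph), oracle.eccentricity(graph), 0),
        (pr.radiality_scores(graph), oracle.radiality(graph), 1e-9),
        (pr.bottleneck_scores(graph), oracle.bottleneck(graph), 0),
    ]
    for got, want, tol in checks:
        for v in graph.nodes:
            if tol:
                assert got[v] == pytest.approx(want[v], abs=tol)
            else:
                assert got[v] == want[v]


@pytest.mark.parametrize("name,graph", random_small_graphs(25, max_n=25, base_seed=99),
                         ids=[f"x{i}" for i in range(25)])
def test_agrees_with_networkx_reference(name, graph):
    """Independent second route: networkx's own centrality implementations."""
    bet = pr.betweenness_scores(graph)
    ref = nx.betweenness_centrality(graph, normalized=False)
    clo = pr.closeness_scores(graph)
    refh = nx.harmonic_centrality(graph)
    for v in graph.nodes:
        assert bet[v] == pytest.approx(ref[v], abs=1e-9)
        assert clo[v] == pytest.approx(refh[v], abs=1e-9)


class TestStructuralProperties:
    @pytest.mark.parametrize("name,graph", random_small_graphs(15, base_seed=5),
                             ids=[f"p{i}" for i in range(15)])
    def test_leaves_carry_no_paths_and_betweenness_below_stress(self, name, graph):
        deg = pr.degree_scores(graph)
        bet = pr.betweenness_scores(graph)
        stress = pr.stress_scores(graph)
        assert sum(deg.values()) == 2 * graph.number_of_edges()
        for v in graph.nodes:
            assert bet[v] <= stress[v] + 1e-9
            if deg[v] <= 1:
                assert bet[v] == 0
                assert stress[v] == 0

    def test_adding_an_edge_never_decreases_degree_or_closeness(self):
        g = nx.gnp_random_graph(10, 0.25, seed=3)
        non_edges = list(nx.non_edges(g))
        assert non_edges
        before_deg, before_clo = pr.degree_scores(g), pr.closeness_scores(g)
        g2 = g.copy()
        g2.add_edge(*non_edges[0])
        after_deg, after_clo = pr.degree_scores(g2), pr.closeness_scores(g2)
        for v in g.nodes:
            assert after_deg[v] >= before_deg[v]
            assert after_clo[v] >= before_clo[v] - 1e-12

    def test_scores_invariant_under_relabeling(self):
        g = nx.gnp_random_graph(11, 0.3, seed=8)
        mapping = {i: f"node-{(i * 7) % 11:02d}" for i in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        for fn in (pr.degree_scores, pr.betweenness_scores, pr.closeness_scores,
                   pr.eccentricity_scores, pr.radiality_scores, pr.stress_scores):
            orig = fn(g)
            relab = fn(h)
            for v in g.nodes:
                assert relab[mapping[v]] == pytest.approx(orig[v], abs=1e-9)


class TestEPC:
    def test_p_one_scores_component_size_minus_one(self):
        g = nx.path_graph(6)
        scores = pr.epc_scores(g, k_realizations=10, p=1.0, seed=1)
        assert all(s == 5.0 for s in scores.values())

    def test_p_zero_scores_zero(self):
        g = nx.complete_graph(5)
        scores = pr.epc_scores(g, k_realizations=10, p=0.0, seed=1)
        assert all(s == 0.0 for s in scores.values())

    def test_same_seed_bit_identical(self):
        g = nx.gnp_random_graph(20, 0.2, seed=2)
        a = pr.epc_scores(g, 200, 0.5, seed=33)
        b = pr.epc_scores(g, 200, 0.5, seed=33)
        assert a == b

    def test_config_validation(self):
        g = nx.path_graph(3)
        with pytest.raises(ConfigurationError):
            pr.epc_scores(g, 10, 1.5, seed=1)
        with pytest.raises(ConfigurationError):
            pr.epc_scores(g, 10, 0.5)  # seed is mandatory
        with pytest.raises(ConfigurationError):
            pr.epc_scores(g, 0, 0.5, seed=1)


class TestComputeAll:
    def test_all_measures_present_and_finite(self):
        table = pr.compute_all(PATH3, seed=7)
        assert set(pr.MEASURES) <= set(table.scores.columns)
        assert np.isfinite(table.scores[list(pr.MEASURES)].to_numpy()).all()
        assert (table.scores[list(pr.MEASURES)].to_numpy() >= 0).all()

    def test_same_seed_identical_table(self, small_truth):
        net = pr.build_network(small_truth.association_list)
        t1 = pr.compute_all(net, seed=5, epc_realizations=50)
        t2 = pr.compute_all(net, seed=5, epc_realizations=50)
        assert t1.scores.equals(t2.scores)

    def test_eccentricity_orientation_flag(self):
        t1 = pr.compute_all(PATH3, seed=1)
        assert not t1.larger_is_central("eccentricity")
        t2 = pr.compute_all(PATH3, seed=1, eccentricity_smaller_is_central=False)
        assert t2.larger_is_central("eccentricity")

    def test_partition_column_filled_for_bipartite_input(self, small_truth):
        net = pr.build_network(small_truth.association_list)
        table = pr.compute_all(net, seed=2, epc_realizations=20)
        parts = set(table.scores["partition"])
        assert parts == {"plant", "metabolite"}
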