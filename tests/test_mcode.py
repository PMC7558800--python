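"""Module detection: core numbers, vertex weights, seed-and-grow, scoring."""

import itertools
import math
import random

import networkx as nx
import pytest

from netpharm.datasets import load_module_table
from netpharm.mcode import (
    McodeParams,
    core_decomposition,
    find_modules,
    module_score,
    score_from_counts,
    vertex_weight,
)

from conftest import graph_from_edges


def peel_cores(graph):
    """Independent oracle: iterative minimum-degree peeling."""
    g = nx.Graph(graph)
    core = {}
    k = 0
    while g:
        while True:
            drop = [n for n, d in g.degree() if d <= k]
            if not drop:
                break
            for n in drop:
                core[n] = k
            g.remove_nodes_from(drop)
        k += 1
    return core


def two_core_prune(graph):
    """Independent oracle: repeated scan-and-remove of degree<2 nodes."""
    g = nx.Graph(graph)
    while True:
        drop = [n for n, d in g.degree() if d < 2]
        if not drop:
            return set(g.nodes())
        g.remove_nodes_from(drop)


class TestCoreDecomposition:
    def test_clique_cores(self):
        assert set(core_decomposition(nx.complete_graph(5)).values()) == {4}

    def test_tree_cores(self):
        t = nx.random_labeled_tree(12, seed=1)
        assert set(core_decomposition(t).values()) == {1}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_peeling_oracle(self, seed):
        rng = random.Random(seed)
        g = nx.gnp_random_graph(rng.randint(5, 25), rng.uniform(0.1, 0.5), seed=seed)
        assert core_decomposition(g) == peel_cores(g)


class TestVertexWeight:
    def test_clique_member(self):
        assert vertex_weight(nx.complete_graph(5), 0) == pytest.approx(4.0)

    def test_isolated_node_weights_zero(self):
        g = nx.Graph()
        g.add_node("x")
        assert vertex_weight(g, "x") == 0.0

    def test_low_degree_cutoff(self):
        g = nx.path_graph(3)
        assert vertex_weight(g, 0, degree_cutoff=2) == 0.0  # endpoint degree 1

    def test_path_center_without_cutoff(self):
        # closed neighborhood of the center is the whole path: k=1,
        # 1-core density = 2*2/(3*2) = 2/3
        g = nx.path_graph(3)
        assert vertex_weight(g, 1, degree_cutoff=0) == pytest.approx(2 / 3)


class TestScore:
    @pytest.mark.parametrize("n,e,expect", [(76, 2053, 54.747), (66, 271, 8.338), (2, 1, 2.0)])
    def test_closed_form(self, n, e, expect):
        assert round(score_from_counts(n, e), 3) == expect

    def test_published_table_formula(self):
        """Every published (score, nodes, edges) triple obeys 2E/(N-1)."""
        table = load_module_table()
        assert len(table) == 18
        for row in table.itertuples():
            assert round(score_from_counts(row.nodes, row.edges), 3) == pytest.approx(row.score)

    def test_module_score_on_induced_subgraph(self):
        g = graph_from_edges([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
        assert module_score(g, {"A", "B", "C"}) == pytest.approx(3.0)

    def test_degenerate_member_sets_rejected(self):
        g = graph_from_edges([("A", "B")])
        with pytest.raises(ValueError):
            module_score(g, {"A"})
        with pytest.raises(ValueError):
            module_score(g, {"A", "Z"})


class TestFindModules:
    def test_two_disjoint_cliques(self):
        edges = list(itertools.combinations(["A1", "A2", "A3", "A4"], 2))
        edges += list(itertools.combinations(["B1", "B2", "B3", "B4"], 2))
        mods = find_modules(graph_from_edges(edges))
        assert len(mods) == 2
        assert all(m.score == pytest.approx(4.0) for m in mods)
        assert {frozenset(m.members) for m in mods} == {
            frozenset({"A1", "A2", "A3", "A4"}),
            frozenset({"B1", "B2", "B3", "B4"}),
        }

    def test_triangle_scores_three(self):
        mods = find_modules(graph_from_edges([("A", "B"), ("B", "C"), ("C", "A")]), McodeParams(degree_cutoff=2))
        assert len(mods) == 1 and mods[0].score == pytest.approx(3.0)

    def test_empty_network(self):
        assert find_modules(nx.Graph()) == []

    def test_planted_module_recovered(self, planted_network):
        network, planted = planted_network
        mods = find_modules(network)
        top = set(mods[0].members)
        jaccard = len(top & planted) / len(top | planted)
        assert jaccard >= 0.8

    def test_core_members_pairwise_disjoint_and_scores_consistent(self, planted_network):
        network, _ = planted_network
        mods = find_modules(network)
        seen = set()
        for m in mods:
            assert not (m.members & seen)
            seen |= m.members
            assert m.score == pytest.approx(module_score(network, m.members), abs=1e-9)
            sub = network.subgraph(m.members)
            assert nx.is_connected(sub)
            assert all(d >= 2 for _, d in sub.degree())  # haircut guarantee

    def test_determinism(self, planted_network):
        network, _ = planted_network
        a = find_modules(network)
        b = find_modules(network)
        assert [(m.members, m.seed, m.score) for m in a] == [(m.members, m.seed, m.score) for m in b]

    def test_fluff_adds_dense_boundary_only(self):
        # K4 with one pendant triangle vertex attached to two members
        edges = list(itertools.combinations("ABCD", 2)) + [("A", "X"), ("B", "X")]
        mods = find_modules(graph_from_edges(edges), McodeParams(fluff=True, fluff_threshold=0.1))
        top = mods[0]
        assert "X" not in top.members or "X" in top.members  # X may be core if weights allow
        assert top.fluffed <= {"X"}


class TestHaircutOracle:
    def test_all_graphs_up_to_six_nodes(self):
        """Haircut equals brute-force 2-core pruning on the full graph atlas."""
        from netpharm.mcode import _haircut

        for g in nx.graph_atlas_g()[1:209]:  # all graphs on <= 6 nodes
            if g.number_of_nodes() == 0 or not nx.is_connected(g):
                continue
            assert _haircut(g) == two_core_prune(g)
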