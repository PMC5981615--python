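import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from _oracles import freq_oracle, fw_mean_reachable
from slnet.graphcore import (UNREACHABLE, DegenerateGraphError,
                             SignalingNetwork, avg_shortest_path_length,
                             candidate_pairs, clean_network, pair_distance,
                             path_frequencies, select_top_fraction)
from slnet.netio import SlnetError


def net_of(edges, cancer=(), nodes=()):
    G = nx.Graph()
    G.add_nodes_from(nodes)
    G.add_edges_from(edges)
    return SignalingNetwork(graph=G, cancer_genes=frozenset(cancer))


class TestCleanNetwork:
    def test_removes_loops_duplicates_orphans(self):
        net = net_of([("A", "A"), ("A", "B"), ("A", "B")], nodes=["C"])
        cleaned = clean_network(net)
        assert cleaned.nodes == {"A", "B"}
        assert cleaned.graph.number_of_edges() == 1

    def test_leaf_prune_can_empty_graph(self):
        with pytest.raises(DegenerateGraphError, match="emptied"):
            clean_network(net_of([("A", "B"), ("B", "C")]), prune_leaves=True)

    def test_k4_unchanged_by_leaf_prune(self):
        net = net_of(nx.complete_graph(4).edges())
        cleaned = clean_network(net, prune_leaves=True)
        assert cleaned.nodes == {0, 1, 2, 3}
        assert cleaned.graph.number_of_edges() == 6

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        G = nx.gnp_random_graph(15, 0.15, seed=seed)
        G.add_edge(3, 3)
        once = clean_network(SignalingNetwork(graph=G))
        twice = clean_network(once)
        assert once.nodes == twice.nodes
        assert set(once.graph.edges()) == set(twice.graph.edges())


class TestPairDistance:
    def test_examples(self, path3):
        assert pair_distance(path3, "A", "C") == 2
        assert pair_distance(path3, "A", "A") == 0

    def test_unreachable_marker(self):
        net = net_of([("A", "B"), ("C", "D")])
        assert pair_distance(net, "A", "C") == UNREACHABLE

    def test_unknown_node_errors(self, path3):
        with pytest.raises(SlnetError, match="unknown"):
            pair_distance(path3, "A", "Z")


class TestAvgShortestPathLength:
    def test_path_graph(self, path3):
        assert avg_shortest_path_length(path3) == pytest.approx(4 / 3)

    def test_complete_graph(self):
        assert avg_shortest_path_length(net_of(nx.complete_graph(4).edges())) == 1.0

    def test_reachable_pair_convention(self):
        # two disjoint edges: only the 2 within-component pairs count
        assert avg_shortest_path_length(net_of([("A", "B"), ("C", "D")])) == 1.0

    def test_strict_mode_rejects_disconnection(self):
        with pytest.raises(DegenerateGraphError):
            avg_shortest_path_length(net_of([("A", "B"), ("C", "D")]), strict=True)

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_floyd_warshall(self, seed):
        """Matches a pure-Python Floyd-Warshall oracle on random graphs
        of up to 12 nodes, connected or not."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        G = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.8)), seed=seed)
        expected = fw_mean_reachable(G.nodes(), G.edges())
        net = SignalingNetwork(graph=G)
        if expected is None:
            with pytest.raises(DegenerateGraphError):
                avg_shortest_path_length(net)
        else:
            assert avg_shortest_path_length(net) == pytest.approx(expected)

    def test_matches_networkx_on_connected_graph(self):
        G = nx.barabasi_albert_graph(40, 2, seed=3)
        ours = avg_shortest_path_length(SignalingNetwork(graph=G))
        assert ours == pytest.approx(nx.average_shortest_path_length(G))


class TestPathFrequencies:
    def test_chain_interior_only(self):
        freq = path_frequencies(net_of([("C1", "X"), ("X", "N1")], cancer=["C1"]))
        assert freq == {"X": 1, "N1": 0}

    def test_star_center(self):
        freq = path_frequencies(
            net_of([("X", "C1"), ("X", "N1"), ("X", "N2")], cancer=["C1"]))
        assert freq == {"X": 2, "N1": 0, "N2": 0}

    def test_diamond_credits_both_routes(self):
        freq = path_frequencies(
            net_of([("C", "A"), ("A", "N"), ("C", "B"), ("B", "N")], cancer=["C"]))
        assert freq == {"A": 1, "B": 1, "N": 0}

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_enumeration_oracle(self, seed):
        """Matches brute-force all-shortest-paths enumeration on random
        graphs of up to 10 nodes."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 11))
        G = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.7)), seed=seed)
        cancer = [int(i) for i in
                  rng.choice(n, size=int(rng.integers(1, n - 1)), replace=False)]
        net = SignalingNetwork(graph=G, cancer_genes=frozenset(cancer))
        assert path_frequencies(net) == freq_oracle(G.nodes(), G.edges(), cancer)


class TestSelectTopFraction:
    def test_ceiling_count(self):
        freq = {f"G{i}": i for i in range(10)}
        assert len(select_top_fraction(freq, 0.3)) == 3

    def test_tie_broken_by_symbol(self):
        assert select_top_fraction({"A": 5, "B": 5, "C": 1}, 1 / 3) == ["A"]

    def test_fraction_one_returns_all(self):
        freq = {"A": 2, "B": 1}
        assert select_top_fraction(freq, 1.0) == ["A", "B"]

    def test_out_of_range_fraction(self):
        with pytest.raises(SlnetError):
            select_top_fraction({"A": 1}, 0.0)

    def test_prefix_and_monotone_in_fraction(self):
        rng = np.random.default_rng(0)
        freq = {f"G{i:02d}": int(rng.integers(0, 6)) for i in range(20)}
        full = select_top_fraction(freq, 1.0)
        prev: list = []
        for frac in (0.1, 0.25, 0.5, 0.75, 1.0):
            sel = select_top_fraction(freq, frac)
            assert sel == full[:len(sel)]
            assert len(sel) >= len(prev)
            prev = sel


class TestCandidatePairs:
    def test_cross_product_count_matches_published_screen(self):
        non_cancer = [f"N{i:04d}" for i in range(740)]
        cancer = [f"C{i:04d}" for i in range(697)]
        pairs = candidate_pairs(non_cancer, cancer)
        assert len(pairs) == 515780

    def test_single_pair_and_order(self):
        assert candidate_pairs(["N1"], ["C1"]) == [("C1", "N1")]
        pairs = candidate_pairs(["N2", "N1"], ["C2", "C1"])
        assert pairs == [("C1", "N1"), ("C1", "N2"), ("C2", "N1"), ("C2", "N2")]

    def test_overlap_errors_with_gene_name(self):
        with pytest.raises(SlnetError, match="G1"):
            candidate_pairs(["G1", "N1"], ["G1", "C1"])
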