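import math

import networkx as nx
import numpy as np
import pytest

from _oracles import fw_mean_reachable, hyper_upper_tail_enum
from slnet.graphcore import SignalingNetwork, candidate_pairs
from slnet.netio import GeneSetCollection, SlnetError
from slnet.screening import (NetworkStabilityScreen, auto_distance_threshold,
                             cumulative_frequency_cutoff,
                             degree_preserving_randomize, distance_screen,
                             empirical_pvalue, enrich, frequency_screen,
                             function_screen, network_screen, stability_score,
                             StabilityRecord)


def net_of(edges, cancer=()):
    return SignalingNetwork(graph=nx.Graph(edges), cancer_genes=frozenset(cancer))


def rec(m="M", n="N", S=0.0, distance=1, p=0.0, **kw):
    return StabilityRecord(m, n, 1.0, 1.0, 1.0, 1.0, S, distance, p=p, **kw)


class TestStabilityScore:
    def test_complete_graph_is_zero(self):
        net = net_of(nx.complete_graph(5).edges(), cancer=[0])
        r = stability_score(net, 0, 1)
        assert r.S == 0.0 and r.D0 == r.Dm == r.Dn == r.Dmn == 1.0

    def test_cycle_adjacent_pair(self, c5_net):
        """C5 with adjacent removals: every intermediate D verified against
        the Floyd-Warshall oracle, S = -4/9."""
        G = c5_net.graph
        r = stability_score(c5_net, "N0", "N1")
        for got, removed in [(r.D0, ()), (r.Dm, ("N0",)), (r.Dn, ("N1",)),
                             (r.Dmn, ("N0", "N1"))]:
            assert got == pytest.approx(
                fw_mean_reachable(G.nodes(), G.edges(), removed=removed))
        assert r.S == pytest.approx(-4 / 9)

    def test_joint_removal_leaving_no_pair_is_degenerate(self):
        net = net_of([("M", "X"), ("N", "X"), ("M", "N")], cancer=["M"])
        r = stability_score(net, "M", "N")
        assert r.degenerate

    def test_rejects_mislabelled_pair(self, c5_net):
        with pytest.raises(SlnetError):
            stability_score(c5_net, "N1", "N2")  # N1 is not a cancer gene

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_floyd_warshall(self, seed):
        G = nx.gnp_random_graph(11, 0.35, seed=seed)
        net = SignalingNetwork(graph=G, cancer_genes=frozenset([0]))
        r = stability_score(net, 0, 1)
        if r.degenerate:
            assert fw_mean_reachable(G.nodes(), G.edges(), removed=(0, 1)) is None
            return
        D0 = fw_mean_reachable(G.nodes(), G.edges())
        Dm = fw_mean_reachable(G.nodes(), G.edges(), removed=(0,))
        Dn = fw_mean_reachable(G.nodes(), G.edges(), removed=(1,))
        Dmn = fw_mean_reachable(G.nodes(), G.edges(), removed=(0, 1))
        assert r.S == pytest.approx((2 * Dmn - Dm - Dn) / D0)


class TestRandomization:
    def test_k3_comes_back_identical(self):
        net = net_of(nx.complete_graph(3).edges())
        out = degree_preserving_randomize(net, seed=0)
        assert set(map(frozenset, out.graph.edges())) == \
            set(map(frozenset, net.graph.edges()))

    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sequence_preserved_and_simple(self, seed):
        G = nx.barabasi_albert_graph(60, 3, seed=seed)
        net = SignalingNetwork(graph=G)
        out = degree_preserving_randomize(net, seed=seed)
        assert sorted(d for _, d in out.graph.degree()) == \
            sorted(d for _, d in G.degree())
        assert nx.number_of_selfloops(out.graph) == 0
        assert out.nodes == net.nodes

    def test_same_seed_reproducible(self):
        net = SignalingNetwork(graph=nx.barabasi_albert_graph(40, 2, seed=1))
        a = degree_preserving_randomize(net, seed=42)
        b = degree_preserving_randomize(net, seed=42)
        assert set(a.graph.edges()) == set(b.graph.edges())

    def test_tiny_graph_returned_unchanged(self):
        net = net_of([("A", "B")])
        out = degree_preserving_randomize(net, seed=0)
        assert set(out.graph.edges()) == {("A", "B")}


class TestEmpiricalPvalue:
    def test_extremes_and_ratio(self):
        null = list(np.linspace(-1, 1, 1000))
        assert empirical_pvalue(2.0, null) == 0.0
        assert empirical_pvalue(-2.0, null) == 1.0
        s = sorted(null)[-51]  # exactly 50 strictly greater
        assert empirical_pvalue(s, null) == 0.05

    def test_empty_null_errors(self):
        with pytest.raises(SlnetError):
            empirical_pvalue(0.0, [])

    def test_pseudocount_avoids_zero(self):
        assert empirical_pvalue(2.0, [0.0] * 99, pseudocount=True) == 0.01


class TestNetworkScreen:
    def test_zero_randomizations_error(self):
        net = net_of(nx.complete_graph(4).edges(), cancer=[0])
        with pytest.raises(SlnetError):
            network_screen(net, [(0, 1)], n_random=0, alpha=0.05, seed=0)

    def test_complete_graph_tie_pathology(self):
        """On a complete graph every S (observed and randomized) is 0, so
        the strict inequality gives p = 0 and every pair passes."""
        net = net_of(nx.complete_graph(6).edges(), cancer=[0])
        out = network_screen(net, [(0, 1), (0, 2)], n_random=20, alpha=0.05, seed=0)
        assert [(r.p, r.S) for r in out] == [(0.0, 0.0), (0.0, 0.0)]

    def test_cached_scores_match_uncached(self, default_bundle):
        """The per-gene D caches give exactly the single-pair evaluation."""
        net = default_bundle.network
        m, n = default_bundle.planted_pairs[0]
        model = NetworkStabilityScreen(net, pairs=[(m, n)], n_random=1)
        records, _ = model._score_network(net)
        single = stability_score(net, m, n)
        assert records[0].S == single.S
        assert (records[0].Dm, records[0].Dn, records[0].Dmn) == \
            (single.Dm, single.Dn, single.Dmn)

    def test_fit_deterministic_for_fixed_seed(self):
        G = nx.barabasi_albert_graph(30, 2, seed=5)
        net = SignalingNetwork(graph=G, cancer_genes=frozenset([0, 1]))
        pairs = [(0, 5), (1, 7), (0, 9)]
        a = NetworkStabilityScreen(net, pairs=pairs, n_random=15).fit(seed=3)
        b = NetworkStabilityScreen(net, pairs=pairs, n_random=15).fit(seed=3)
        assert a.records == b.records

    def test_summary_mentions_counts(self):
        net = net_of(nx.complete_graph(6).edges(), cancer=[0])
        res = NetworkStabilityScreen(net, n_random=5).fit(seed=0)
        text = res.summary()
        assert "candidate pairs: 5" in text
        assert "degree-preserving" in text


class TestDistanceScreen:
    def test_auto_threshold_floors_mean(self):
        # mean distance 2.90 -> threshold 2
        distances = [2] * 10 + [3] * 90
        assert sum(distances) / len(distances) == pytest.approx(2.90)
        assert auto_distance_threshold(distances) == 2

    def test_drops_beyond_threshold(self):
        records = [rec(distance=3), rec(n="N2", distance=2)]
        kept = distance_screen(records, threshold=2)
        assert [r.non_cancer_gene for r in kept] == ["N2"]

    def test_threshold_at_diameter_is_identity(self):
        records = [rec(distance=d, n=f"N{d}") for d in (1, 2, 3)]
        assert distance_screen(records, threshold=3) == records


class TestFrequencyCutoff:
    @pytest.mark.parametrize("fraction,expected", [
        (0.5, ["A"]),
        (0.8, ["A", "B"]),
        (1.0, ["A", "B", "C"]),
    ])
    def test_mass_prefix(self, fraction, expected):
        assert cumulative_frequency_cutoff({"A": 5, "B": 3, "C": 2}, fraction) == expected

    def test_out_of_range_errors(self):
        with pytest.raises(SlnetError):
            cumulative_frequency_cutoff({"A": 1}, 0.0)

    def test_frequency_screen_filters_by_kept_genes(self):
        records = [rec(n="N1"), rec(n="N2")]
        assert frequency_screen(records, ["N1", "N2"]) == records
        assert frequency_screen(records, []) == []
        assert [r.non_cancer_gene for r in frequency_screen(records, ["N2"])] == ["N2"]


class TestEnrich:
    def background(self, n=10):
        return {f"G{i}" for i in range(n)}

    def test_two_of_two_in_three_set(self):
        """k=2 draws both inside a 3-gene set from a 10-gene background:
        p = C(3,2)/C(10,2) = 3/45, confirmed by exhaustive enumeration."""
        coll = GeneSetCollection(sets={"S": ("d", frozenset({"G0", "G1", "G2"}))})
        out = enrich({"G0", "G1"}, coll, self.background())
        assert out[0].p == pytest.approx(3 / 45)
        assert out[0].p == pytest.approx(hyper_upper_tail_enum(10, 3, 2, 2))

    def test_no_overlap_is_p_one(self):
        coll = GeneSetCollection(sets={"S": ("d", frozenset({"G8", "G9"}))})
        assert enrich({"G0"}, coll, self.background()).pop().p == 1.0

    def test_certain_event_is_p_one(self):
        bg = self.background(4)
        coll = GeneSetCollection(sets={"S": ("d", frozenset(bg))})
        assert enrich({"G0", "G1"}, coll, bg).pop().p == 1.0

    def test_query_outside_background_errors(self):
        coll = GeneSetCollection(sets={"S": ("d", frozenset({"G0"}))})
        with pytest.raises(SlnetError):
            enrich({"ZZZ"}, coll, self.background())

    @pytest.mark.parametrize("N,K,n", [(6, 2, 3), (8, 3, 4), (10, 4, 3), (12, 5, 4)])
    def test_agrees_with_enumeration(self, N, K, n):
        bg = {f"G{i}" for i in range(N)}
        coll = GeneSetCollection(sets={"S": ("d", frozenset(f"G{i}" for i in range(K)))})
        for k_target in range(0, min(K, n) + 1):
            query = {f"G{i}" for i in range(k_target)} | \
                    {f"G{K + i}" for i in range(n - k_target)}
            out = enrich(query, coll, bg)
            assert out[0].overlap == k_target
            assert out[0].p == pytest.approx(
                hyper_upper_tail_enum(N, K, n, k_target) if k_target else 1.0)

    def test_bh_adjustment_is_monotone_and_bounded(self):
        sets = {f"S{i}": ("d", frozenset({f"G{i}", f"G{i+1}"})) for i in range(5)}
        out = enrich({"G0", "G1", "G2"}, GeneSetCollection(sets=sets),
                     self.background(12))
        for r in out:
            assert r.q >= r.p - 1e-12
            assert 0 <= r.q <= 1


class TestFunctionScreen:
    def make(self):
        coll = GeneSetCollection(sets={"S": ("d", frozenset({"M", "N"}))})
        enr_sig = [type("E", (), {"set_id": "S", "q": 0.001})]
        enr_null = [type("E", (), {"set_id": "S", "q": 0.9})]
        return coll, enr_sig, enr_null

    def test_no_significant_set_empties_output(self):
        coll, _, enr_null = self.make()
        assert function_screen([rec()], enr_null, coll) == []

    def test_pair_with_both_genes_in_significant_set_kept(self):
        coll, enr_sig, _ = self.make()
        assert function_screen([rec()], enr_sig, coll) == [rec()]

    def test_one_sided_membership_drops_pair(self):
        coll, enr_sig, _ = self.make()
        assert function_screen([rec(n="OTHER")], enr_sig, coll) == []
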