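import networkx as nx
import numpy as np
import pytest

from netmend.community import Partition
from netmend.ranking import RankedList
from netmend.splits_eval import (
    auc,
    intra_inter_counts,
    mean_predicted_betweenness,
    precision_at_L,
    split_edges,
)

from oracles import total_ordered_distance


@pytest.fixture
def ten_edge_graph():
    g = nx.cycle_graph(10)
    assert g.number_of_edges() == 10
    return g


class TestSplitEdges:
    def test_ninety_ten(self, ten_edge_graph):
        s = split_edges(ten_edge_graph, (0.9, 0.0, 0.1), seed=0)
        assert (len(s.train), len(s.learn), len(s.probe)) == (9, 0, 1)

    def test_eighty_ten_ten(self, ten_edge_graph):
        s = split_edges(ten_edge_graph, (0.8, 0.1, 0.1), seed=0)
        assert (len(s.train), len(s.learn), len(s.probe)) == (8, 1, 1)

    def test_disjoint_union_and_determinism(self, karate):
        s1 = split_edges(karate, (0.8, 0.1, 0.1), seed=5)
        s2 = split_edges(karate, (0.8, 0.1, 0.1), seed=5)
        s3 = split_edges(karate, (0.8, 0.1, 0.1), seed=6)
        parts = [set(s1.train), set(s1.learn), set(s1.probe)]
        assert sum(len(p) for p in parts) == karate.number_of_edges()
        assert set.union(*parts) == {
            tuple(sorted(e, key=str)) for e in karate.edges()
        }
        assert (s1.train, s1.learn, s1.probe) == (s2.train, s2.learn, s2.probe)
        assert s1.probe != s3.probe

    def test_train_graph_keeps_all_nodes(self, karate):
        s = split_edges(karate, (0.9, 0.0, 0.1), seed=1)
        assert s.train_graph().number_of_nodes() == karate.number_of_nodes()

    def test_bad_fractions_rejected(self, ten_edge_graph):
        with pytest.raises(ValueError):
            split_edges(ten_edge_graph, (0.8, 0.1, 0.2), seed=0)


class TestAuc:
    def test_all_probe_on_top(self):
        r = RankedList([("p", "1"), ("p", "2"), ("x", "1"), ("x", "2")])
        assert auc(r, [("p", "1"), ("p", "2")], [("x", "1"), ("x", "2")]) == 1.0

    def test_all_tied_is_half(self):
        pairs = [("p", "1"), ("x", "1"), ("p", "2"), ("x", "2")]
        r = RankedList(pairs, scores=[1.0, 1.0, 1.0, 1.0])
        assert auc(r, [("p", "1"), ("p", "2")], [("x", "1"), ("x", "2")]) == 0.5

    def test_worked_example_three_quarters(self):
        # alternating probe/nonexistent: 3 of 4 comparisons favour the probe
        r = RankedList([("p", "1"), ("x", "1"), ("p", "2"), ("x", "2")])
        assert auc(r, [("p", "1"), ("p", "2")], [("x", "1"), ("x", "2")]) == 0.75

    def test_empty_sets_rejected(self):
        r = RankedList([("a", "b")])
        with pytest.raises(ValueError):
            auc(r, [], [("a", "b")])

    def test_pair_missing_from_ranking_rejected(self):
        r = RankedList([("a", "b")])
        with pytest.raises(KeyError):
            auc(r, [("a", "b")], [("c", "d")])

    def test_sampled_close_to_exhaustive(self):
        rng = np.random.default_rng(0)
        pairs = [("n", str(i)) for i in range(200)]
        scores = rng.random(200).tolist()
        order = np.argsort(scores)[::-1]
        r = RankedList(
            [pairs[i] for i in order], [scores[i] for i in order]
        )
        probe = pairs[:40]
        nonex = pairs[40:]
        exact = auc(r, probe, nonex)
        n = 100_000
        sampled = auc(r, probe, nonex, sample_n=n, seed=1)
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(sampled - exact) <= 3 * se + 1e-9

    def test_invariant_to_node_relabeling(self):
        r1 = RankedList([("a", "b"), ("c", "d"), ("e", "f")])
        r2 = RankedList([("A", "B"), ("C", "D"), ("E", "F")])
        v1 = auc(r1, [("a", "b")], [("c", "d"), ("e", "f")])
        v2 = auc(r2, [("A", "B")], [("C", "D"), ("E", "F")])
        assert v1 == v2


class TestPrecision:
    def test_perfect(self):
        r = RankedList([("a", "b"), ("c", "d")])
        assert precision_at_L(r, [("a", "b"), ("c", "d")]) == 1.0

    def test_zero(self):
        r = RankedList([("a", "b"), ("c", "d")])
        assert precision_at_L(r, [("x", "y")], L=2) == 0.0

    def test_three_of_four(self):
        r = RankedList([("a", "1"), ("a", "2"), ("a", "3"), ("a", "4")])
        probe = [("a", "1"), ("a", "2"), ("a", "3"), ("b", "9")]
        assert precision_at_L(r, probe, L=4) == 0.75

    def test_zero_L_rejected(self):
        with pytest.raises(ValueError):
            precision_at_L(RankedList([("a", "b")]), [], L=0)


class TestMeanPredictedBetweenness:
    def test_bridge_between_triangles(self, two_triangles):
        # adding the 0-3 bridge: all 2*3*3 ordered cross pairs traverse it
        b = mean_predicted_betweenness(two_triangles, RankedList([(0, 3)]))
        assert b == pytest.approx(18.0)

    def test_closing_a_triangle(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        b = mean_predicted_betweenness(g, RankedList([("a", "c")]))
        assert b == pytest.approx(2.0)

    def test_mean_of_two_links_with_conservation(self, two_triangles):
        predicted = RankedList([(0, 3), (2, 5)])
        b = mean_predicted_betweenness(two_triangles, predicted)
        aug = two_triangles.copy()
        aug.add_edges_from(predicted.pairs)
        from netmend.graph_core import edge_betweenness

        eb = edge_betweenness(aug)
        assert sum(eb.values()) == pytest.approx(total_ordered_distance(aug))
        assert b == pytest.approx((eb[(0, 3)] + eb[(2, 5)]) / 2)

    def test_existing_edge_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            mean_predicted_betweenness(two_triangles, RankedList([(0, 1)]))

    def test_empty_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            mean_predicted_betweenness(two_triangles, RankedList([]))


class TestIntraInterCounts:
    def test_counts(self):
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        predicted = RankedList([("a", "b"), ("a", "c"), ("c", "d")])
        probe = [("a", "b"), ("a", "c")]
        # (a,b) intra+hit, (a,c) inter+hit, (c,d) intra+miss
        assert intra_inter_counts(predicted, probe, p) == (2, 1, 1, 1)

    def test_all_intra(self):
        p = Partition({"a": 0, "b": 0, "c": 0})
        predicted = RankedList([("a", "b"), ("b", "c")])
        n_i, n_o, c_i, c_o = intra_inter_counts(predicted, [], p)
        assert (n_i, n_o) == (2, 0) and (c_i, c_o) == (0, 0)
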