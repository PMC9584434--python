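import pytest

from oscnet.core import ACTIVATION, EdgeHypothesis, RankingTable
from oscnet.netrank import (EdgePrevalence, NetworkScore, TopNetworkCriteria,
                            compare_rankings, edge_prevalence,
                            global_edge_ranking, select_top_networks)
from oscnet.netspec import RegulatoryNetwork


def net_of(*keys):
    return RegulatoryNetwork.from_edges([EdgeHypothesis.from_key(k)
                                         for k in keys])


def score(nid, osc, pm, flags=None, keys=("A->B", "B->A")):
    return NetworkScore(nid, net_of(*keys), osc, pm,
                        flags or {"rep1": pm > 0})


class TestSelectTopNetworks:
    def test_threshold_boundary_excludes_just_below(self):
        crit = TopNetworkCriteria(1.0, 1.0, 0.5)
        assert not crit.admits(score("n", 1.0, 0.49))
        assert crit.admits(score("n", 1.0, 0.5))

    def test_replicate_rule_requires_all(self):
        crit = TopNetworkCriteria(0.1, 0.4, 1.0, require_all_replicates=True)
        one = score("n", 0.3, 1.0, {"rep1": True, "rep2": False})
        both = score("n", 0.3, 1.0, {"rep1": True, "rep2": True})
        assert not crit.admits(one)
        assert crit.admits(both)

    def test_selection_equals_set_comprehension_oracle(self):
        crit = TopNetworkCriteria(0.5, 1.0, 0.6)
        scores = [score(f"n{i}", o, p) for i, (o, p) in enumerate(
            [(1.0, 0.7), (0.4, 0.9), (0.6, 0.5), (0.8, 0.61), (0.5, 0.6)])]
        got = {s.network_id for s in select_top_networks(scores, crit)}
        expected = {s.network_id for s in scores
                    if 0.5 <= s.oscillation_score <= 1.0
                    and s.pattern_match_score >= 0.6}
        assert got == expected

    def test_malformed_window_rejected(self):
        with pytest.raises(ValueError, match="lo > hi"):
            TopNetworkCriteria(0.9, 0.1)

    def test_pattern_match_without_oscillation_rejected(self):
        with pytest.raises(ValueError):
            NetworkScore("n", net_of("A->B", "B->A"), 0.0, 0.5, {})


class TestEdgePrevalence:
    def test_arithmetic(self):
        tops = [score(f"n{i}", 1.0, 1.0, keys=k) for i, k in enumerate([
            ("A->B", "B->A"), ("A->B", "B->A"), ("A->B", "B-|A", "A->A"),
            ("A->B", "B->A")])]
        cands = [EdgeHypothesis.from_key(k)
                 for k in ("A->B", "B->A", "B-|A", "C->C")]
        prev = {p.edge.key: p for p in edge_prevalence(tops, cands)}
        assert prev["A->B"].prevalence == 1.0
        assert prev["B->A"].prevalence == 0.75
        assert prev["B-|A"].prevalence == 0.25
        assert prev["C->C"].prevalence == 0.0

    def test_conservation_of_counts(self):
        tops = [score("a", 1.0, 1.0, keys=("A->B", "B->A")),
                score("b", 1.0, 1.0, keys=("A->B", "B-|A"))]
        cands = [EdgeHypothesis.from_key(k) for k in ("A->B", "B->A", "B-|A")]
        prevs = edge_prevalence(tops, cands)
        assert sum(p.n_present for p in prevs) == \
            sum(len(t.network.edges) for t in tops)


class TestGlobalEdgeRanking:
    def _local(self):
        return RankingTable([("A->B", 0.9, 1), ("B->A", 0.8, 2),
                             ("A-|B", 0.7, 3), ("B-|A", 0.6, 4)],
                            "higher_is_better", "")

    def test_prevalence_ties_broken_by_local_rank(self):
        prevs = [EdgePrevalence(EdgeHypothesis.from_key("A-|B"), 2, 4),
                 EdgePrevalence(EdgeHypothesis.from_key("B->A"), 2, 4),
                 EdgePrevalence(EdgeHypothesis.from_key("A->B"), 3, 4)]
        table = global_edge_ranking(prevs, self._local())
        assert table.keys[:3] == ["A->B", "B->A", "A-|B"]

    def test_zero_prevalence_edges_share_worst_rank(self):
        prevs = [EdgePrevalence(EdgeHypothesis.from_key("A->B"), 1, 2),
                 EdgePrevalence(EdgeHypothesis.from_key("B->A"), 0, 2),
                 EdgePrevalence(EdgeHypothesis.from_key("A-|B"), 0, 2),
                 EdgePrevalence(EdgeHypothesis.from_key("B-|A"), 2, 2)]
        table = global_edge_ranking(prevs, self._local())
        assert table.rank_of("B->A") == 4.0
        assert table.rank_of("A-|B") == 4.0
        assert table.rank_of("B-|A") == 1.0

    def test_matches_sort_with_key_oracle(self, rng):
        local = self._local()
        counts = {k: int(c) for k, c in
                  zip(local.keys, rng.integers(0, 5, size=4))}
        prevs = [EdgePrevalence(EdgeHypothesis.from_key(k), c, 4)
                 for k, c in counts.items()]
        table = global_edge_ranking(prevs, local)
        nonzero = [k for k in counts if counts[k] > 0]
        expected = sorted(nonzero,
                          key=lambda k: (-counts[k], local.rank_of(k)))
        assert table.keys[:len(expected)] == expected


class TestCompareRankings:
    def test_identical_rankings_give_zero_delta(self):
        local = RankingTable([("A->B", 0.9, 1), ("B->A", 0.8, 2)],
                             "higher_is_better", "")
        rows = compare_rankings(local, local, ["A", "B"], ["A->B", "B->A"])
        assert all(r.delta == 0.0 for r in rows)

    def test_hand_three_node_example_matches_median_oracle(self):
        local = RankingTable([("A->B", 0.9, 1), ("B->C", 0.8, 2),
                              ("C->A", 0.7, 3)], "higher_is_better", "")
        glob = RankingTable([("B->C", 1.0, 1), ("C->A", 0.5, 2),
                             ("A->B", 0.2, 3)], "higher_is_better", "")
        rows = {r.node: r for r in compare_rankings(
            local, glob, ["A", "B", "C"], ["A->B", "B->C", "C->A"])}
        # A incident to A->B (1 / 3) and C->A (3 / 2): medians 2 / 2.5
        assert rows["A"].local_score == 2.0
        assert rows["A"].global_score == 2.5
        assert rows["A"].delta == pytest.approx(-0.5)

    def test_empty_restriction_rejected(self):
        local = RankingTable([("A->B", 0.9, 1)], "higher_is_better", "")
        with pytest.raises(ValueError, match="empty"):
            compare_rankings(local, local, ["A"], [])
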