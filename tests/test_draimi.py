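"""DRAIMI: decile split, bootstrap ratio ranking, and pivot scoring."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, seed as hypo_seed, settings
from hypothesis import strategies as st

from anchorscope import (
    DataError,
    DraimiConfig,
    PPIGraph,
    PivotScore,
    RatioStat,
    draimi_cross_cohort,
    ratio_stats,
    run_draimi,
    score_pivots,
    select_top_ratios,
    split_deciles,
)
from anchorscope._util import round_half_away

from conftest import make_matrix


def _stat(a, b, t=1.0, cons=1.0, rank=1):
    return RatioStat(pair=(a, b), t_abs=t, consistency=cons, final_rank=rank)


def brute_force_pivot_scores(pairs, graph: PPIGraph):
    """Independent oracle: literal double loop over nodes and ratios."""
    out = {}
    for g in graph.graph.nodes:
        deg = graph.graph.degree(g)
        if deg == 0:
            continue
        hits = 0
        for a, b in pairs:
            if g != a and g != b and graph.graph.has_edge(g, a) and graph.graph.has_edge(g, b):
                hits += 1
        out[g] = (hits, deg)
    return out


class TestSplitDeciles:
    def _matrix(self, values, samples=None):
        return make_matrix([values], genes=["ANCH"], samples=samples, scale_state="log")

    def test_floor_arithmetic_n20(self):
        m = self._matrix(list(range(20)))
        up, lo = split_deciles(m, "ANCH", DraimiConfig())
        assert len(up) == 2 and len(lo) == 2

    def test_minimum_group_size_one(self):
        m = self._matrix(list(range(10)))
        up, lo = split_deciles(m, "ANCH", DraimiConfig())
        assert len(up) == len(lo) == 1
        assert any("unstable" in w for w in m.warnings)

    def test_extremes_by_full_sort(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.arange(1.0, 101.0))
        m = self._matrix(list(vals))
        up, lo = split_deciles(m, "ANCH", DraimiConfig())
        assert sorted(vals[[m.sample_ids.index(s) for s in up]]) == list(range(91, 101))
        assert sorted(vals[[m.sample_ids.index(s) for s in lo]]) == list(range(1, 11))

    def test_boundary_ties_break_lexicographically_and_stay_disjoint(self):
        m = self._matrix([5.0, 5.0, 5.0, 5.0], samples=["sd", "sc", "sb", "sa"])
        cfg = DraimiConfig(decile_fraction=0.25)
        up, lo = split_deciles(m, "ANCH", cfg)
        assert lo == ["sa"] and up == ["sd"]

    def test_groups_disjoint(self):
        m = self._matrix(list(range(30)))
        up, lo = split_deciles(m, "ANCH", DraimiConfig(decile_fraction=0.5))
        assert not set(up) & set(lo)


class TestRatioStats:
    def _fixture(self, seed=0, shift=0.0):
        """4-gene set, upper/lower groups of 8; pair (A,B) log-ratio shifted.

        The shift is split antisymmetrically (+shift/2 on A, -shift/2 on B in
        the upper group) so (A,B) carries the full shift while pairs sharing
        one member carry only half of it.
        """
        rng = np.random.default_rng(seed)
        vals = rng.normal(6, 0.5, size=(5, 16))
        vals[0] = np.linspace(0, 10, 16)  # anchor: first 8 low, last 8 high
        vals[1, 8:] += shift / 2
        vals[2, 8:] -= shift / 2
        m = make_matrix(vals, genes=["ANCH", "A", "B", "C", "D"], scale_state="log")
        upper = [f"s{j}" for j in range(8, 16)]
        lower = [f"s{j}" for j in range(8)]
        return m, upper, lower

    def test_identical_groups_give_zero_t(self):
        m, upper, lower = self._fixture()
        m.data.loc["A"] = 1.0  # constant difference everywhere
        m.data.loc["B"] = 0.5
        cfg = DraimiConfig(gene_set=("A", "B"), n_bootstrap=5, seed=0)
        stats = ratio_stats(m, upper, lower, cfg)
        assert stats[0].t_abs == 0.0

    def test_gene_order_within_pair_is_canonical(self):
        m, upper, lower = self._fixture(shift=2.0)
        cfg = DraimiConfig(gene_set=("B", "A"), n_bootstrap=5, seed=0)
        stats = ratio_stats(m, upper, lower, cfg)
        assert all(s.pair[0] < s.pair[1] for s in stats)

    def test_planted_pair_ranks_first_with_full_consistency(self):
        # 6 pooled-SD shift on (A,B) against the 5 other pairs among {A,B,C,D}
        m, upper, lower = self._fixture(seed=1, shift=6 * 0.5 * math.sqrt(2))
        cfg = DraimiConfig(gene_set=("A", "B", "C", "D"), n_bootstrap=50, per_bootstrap_k=1, seed=2)
        stats = ratio_stats(m, upper, lower, cfg)
        assert len(stats) == 6
        top = min(stats, key=lambda s: s.final_rank)
        assert top.pair == ("A", "B")
        assert top.consistency == 1.0

    def test_consistency_stays_one_when_bootstrap_count_grows(self):
        # (A,B) dominates so thoroughly that it ranks inside the top 3 of 6
        # pairs in every replicate; its consistency must then be exactly 1.0
        # regardless of how many bootstrap replicates are drawn
        m, upper, lower = self._fixture(seed=3, shift=8.0)
        ranks = []
        for nb in (20, 200):
            cfg = DraimiConfig(gene_set=("A", "B", "C", "D"), n_bootstrap=nb, per_bootstrap_k=3, seed=4)
            stats = ratio_stats(m, upper, lower, cfg)
            top = min(stats, key=lambda s: s.final_rank)
            ranks.append((top.pair, top.consistency))
        assert ranks[0] == (("A", "B"), 1.0) and ranks[1] == (("A", "B"), 1.0)

    def test_too_small_gene_set_rejected(self):
        m, upper, lower = self._fixture()
        with pytest.raises(DataError, match="at least 2"):
            ratio_stats(m, upper, lower, DraimiConfig(gene_set=("A", "ZZZ")))

    def test_relabeling_permutes_outputs_identically(self):
        m, upper, lower = self._fixture(seed=5, shift=2.0)
        cfg = DraimiConfig(gene_set=("A", "B", "C", "D"), n_bootstrap=30, seed=6)
        base = ratio_stats(m, upper, lower, cfg)
        # order-preserving relabeling keeps lexicographic tie-breaks aligned
        relabel = {"A": "A2", "B": "B2", "C": "C2", "D": "D2", "ANCH": "ANCH"}
        m2 = make_matrix(
            m.data.to_numpy(), genes=[relabel[g] for g in m.gene_ids],
            samples=m.sample_ids, scale_state="log",
        )
        cfg2 = dataclasses.replace(cfg, gene_set=("A2", "B2", "C2", "D2"))
        perm = ratio_stats(m2, upper, lower, cfg2)
        for s1, s2 in zip(base, perm):
            assert (relabel[s1.pair[0]], relabel[s1.pair[1]]) == s2.pair
            assert s1.final_rank == s2.final_rank
            assert s1.consistency == s2.consistency


class TestSelectTop:
    def test_k_exceeding_pair_count_returns_all(self):
        stats = [_stat("A", "B", rank=1), _stat("C", "D", rank=2)]
        assert len(select_top_ratios(stats, DraimiConfig(top_k=1000))) == 2

    def test_k_one_returns_rank_one_pair(self):
        stats = [_stat("C", "D", rank=2), _stat("A", "B", rank=1)]
        top = select_top_ratios(stats, DraimiConfig(top_k=1))
        assert top == [stats[1]]


class TestScorePivots:
    def test_worked_example_two_of_three_hits(self):
        g = PPIGraph()
        for leaf in "ABC":
            g.add_edge("P", leaf)
        g.add_edge("D", "A")  # give D a degree so it is scored too
        top = [_stat("A", "B"), _stat("A", "C"), _stat("B", "D")]
        scores = {s.gene: s for s in score_pivots(top, g)}
        assert scores["P"].hits == 2
        assert scores["P"].degree == 3
        assert scores["P"].intermediary_ratio == pytest.approx(2 / 3)

    def test_empty_top_list_scores_everything_zero(self):
        g = PPIGraph()
        g.add_edge("A", "B")
        assert all(s.intermediary_ratio == 0 for s in score_pivots([], g))

    def test_pair_membership_excludes_the_candidate(self):
        g = PPIGraph()
        g.add_edge("A", "B")
        g.add_edge("A", "C")
        scores = {s.gene: s for s in score_pivots([_stat("A", "B")], g)}
        assert scores["A"].hits == 0  # A is a member of the only top pair

    def test_degree_denominator_can_be_restricted_to_gene_set(self):
        g = PPIGraph()
        for leaf in ("A", "B", "OUT1", "OUT2"):
            g.add_edge("P", leaf)
        top = [_stat("A", "B")]
        full = {s.gene: s for s in score_pivots(top, g)}
        assert full["P"].degree == 4 and full["P"].intermediary_ratio == 0.25
        restricted = {s.gene: s for s in score_pivots(top, g, restrict_degree_to={"A", "B"})}
        assert restricted["P"].degree == 2 and restricted["P"].intermediary_ratio == 0.5
        # nodes with no neighbor inside the set are dropped entirely
        assert "OUT1" not in restricted

    @settings(deadline=None, max_examples=200)
    @hypo_seed(1234)
    @given(st.data())
    def test_matches_brute_force_on_random_toys(self, data):
        nodes = [f"N{i}" for i in range(data.draw(st.integers(2, 15)))]
        g = PPIGraph()
        g.graph.add_nodes_from(nodes)
        for a, b in data.draw(
            st.lists(st.tuples(st.sampled_from(nodes), st.sampled_from(nodes)), max_size=40)
        ):
            g.add_edge(a, b)
        pairs = data.draw(
            st.lists(
                st.tuples(st.sampled_from(nodes), st.sampled_from(nodes)).filter(lambda t: t[0] != t[1]),
                max_size=20, unique=True,
            )
        )
        top = [_stat(a, b) for a, b in pairs]
        expected = brute_force_pivot_scores(pairs, g)
        got = {s.gene: s for s in score_pivots(top, g)} if g.n_edges else {}
        if g.graph.number_of_nodes() == 0:
            return
        assert set(got) == set(expected)
        for gene, (hits, deg) in expected.items():
            assert got[gene].hits == hits
            assert got[gene].degree == deg
            assert got[gene].intermediary_ratio == hits / deg
            assert got[gene].intermediary_ratio >= 0.0

    def test_ratio_can_exceed_one_in_dense_neighborhoods(self):
        # hits counts qualifying ratios, bounded by top_k (not by degree):
        # when more top ratios nest inside a node's neighborhood than it has
        # edges, the score exceeds 1.  Sparse high-confidence networks with
        # top_k small relative to the pair universe stay within [0, 1].
        g = PPIGraph()
        for leaf in "ABC":
            g.add_edge("HUB", leaf)
        top = [_stat("A", "B"), _stat("A", "C"), _stat("B", "C"), _stat("A", "HUB")]
        scores = {s.gene: s for s in score_pivots(top, g)}
        assert scores["HUB"].hits == 3 and scores["HUB"].degree == 3
        assert scores["HUB"].intermediary_ratio == 1.0
        g.add_edge("HUB", "D")
        g.add_edge("A", "D")
        top += [_stat("A", "D"), _stat("B", "D"), _stat("C", "D")]
        scores = {s.gene: s for s in score_pivots(top, g)}
        assert scores["HUB"].hits == 6 and scores["HUB"].degree == 4
        assert scores["HUB"].intermediary_ratio == 1.5


class TestCrossCohort:
    def _score(self, gene, ratio, hits=1, degree=2):
        return PivotScore(gene=gene, hits=hits, degree=degree, intermediary_ratio=ratio)

    def test_printed_row_keeps_both_cohort_values(self):
        rows = draimi_cross_cohort([self._score("NGF", 0.24)], [self._score("NGF", 0.23)])
        assert rows[0]["score_a"] == 0.24 and rows[0]["score_b"] == 0.23

    def test_gene_in_one_cohort_only_is_dropped(self):
        rows = draimi_cross_cohort([self._score("ONLYA", 0.5)], [self._score("ONLYB", 0.5)])
        assert rows == []

    def test_printed_mean_value(self):
        rows = draimi_cross_cohort([self._score("MET", 0.17)], [self._score("MET", 0.11)])
        assert round_half_away(rows[0]["mean"], 2) == 0.14


def test_end_to_end_planted_pivot_recovers_truth_score(planted_spec, cohort_a_log):
    from anchorscope import generate_ppi, generate_truth, immunity_gene_set

    graph = generate_ppi(planted_spec)
    cfg = DraimiConfig(gene_set=tuple(immunity_gene_set(planted_spec, extra=8)), seed=11)
    _top, scores = run_draimi(cohort_a_log, planted_spec.anchor_id, graph, cfg)
    truth = generate_truth(planted_spec).pivots.iloc[0]
    assert scores[0].gene == truth.pivot
    assert scores[0].intermediary_ratio == truth.intermediary_ratio


def test_end_to_end_seeded_determinism(planted_spec, cohort_a_log):
    from anchorscope import generate_ppi, immunity_gene_set

    graph = generate_ppi(planted_spec)
    cfg = DraimiConfig(gene_set=tuple(immunity_gene_set(planted_spec, extra=8)), seed=11)
    out1 = run_draimi(cohort_a_log, planted_spec.anchor_id, graph, cfg)
    out2 = run_draimi(cohort_a_log, planted_spec.anchor_id, graph, cfg)
    assert out1 == out2
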