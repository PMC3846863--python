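import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crengine import (
    CausalGraph,
    CausalStatement,
    DEProfile,
    Hypothesis,
    HypothesisResult,
    count_outcomes,
    correctness_pvalue_exact,
    correctness_pvalue_mc,
    downstream_predictions,
    enrichment_pvalue,
    rank_and_filter,
    score_all_hypotheses,
)
from crengine.knowledgebase import PredictionSet, AMBIGUOUS
from crengine.scoring import ScoringError

from conftest import correctness_tail_by_enumeration, random_graph, random_profile


def make_result(entity, sign, score, n_correct, enr, cor):
    return HypothesisResult(
        Hypothesis(entity, sign), q_plus=score + 5, q_minus=0, q_ambig=0,
        n_correct=n_correct, n_incorrect=n_correct - score,
        n_ambig_changed=0, score=score, enrichment_p=enr, correctness_p=cor,
    )


class TestCountOutcomes:
    def test_direct_counts(self):
        pred = PredictionSet("h", 1, {"t1": 1, "t2": 1, "t3": -1}, 2)
        profile = DEProfile(frozenset({"t1", "t2", "t3"}), {"t1": 1, "t2": -1})
        q_plus, q_minus, q_ambig, n_corr, n_inc, n_amb = count_outcomes(
            pred, profile
        )
        assert (q_plus, q_minus, q_ambig) == (2, 1, 0)
        assert (n_corr, n_inc, n_amb) == (1, 1, 0)

    def test_all_unchanged_scores_zero(self):
        pred = PredictionSet("h", 1, {"t1": 1, "t2": -1}, 2)
        profile = DEProfile(frozenset({"t1", "t2"}), {})
        assert count_outcomes(pred, profile)[3:5] == (0, 0)

    def test_ambiguous_excluded_from_outcomes(self):
        pred = PredictionSet("h", 1, {"t": AMBIGUOUS}, 2)
        profile = DEProfile(frozenset({"t"}), {"t": 1})
        q_plus, q_minus, q_ambig, n_corr, n_inc, n_amb = count_outcomes(
            pred, profile
        )
        assert (q_ambig, n_amb) == (1, 1)
        assert (n_corr, n_inc) == (0, 0)

    def test_unmeasured_predictions_dropped(self):
        pred = PredictionSet("h", 1, {"t": 1, "not_measured": 1}, 2)
        profile = DEProfile(frozenset({"t"}), {"t": 1})
        assert count_outcomes(pred, profile)[0] == 1


class TestEnrichment:
    def test_zero_hits_is_one(self):
        assert enrichment_pvalue(10, 5, 4, 0) == 1.0

    def test_certain_event_is_one(self):
        assert enrichment_pvalue(10, 5, 10, 5) == 1.0

    def test_hand_enumerated_tail(self):
        # P(X >= 4) for N=10, m=5, K=4: only X=4, C(5,4)/C(10,4) = 5/210
        assert enrichment_pvalue(10, 5, 4, 4) == pytest.approx(5 / 210, rel=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ScoringError):
            enrichment_pvalue(10, 5, 4, 5)
        with pytest.raises(ScoringError):
            enrichment_pvalue(10, 12, 4, 2)

    def test_never_reports_zero(self):
        assert enrichment_pvalue(10_000, 5000, 2000, 2000) > 0.0


class TestCorrectnessExact:
    def test_single_slot_single_call(self):
        assert correctness_pvalue_exact(1, 0, 1, 0, 2, 1) == pytest.approx(0.5)

    def test_minimal_score_tail_is_one(self):
        assert correctness_pvalue_exact(3, 2, 2, 2, 9, -5) == 1.0

    def test_impossible_score_rejected(self):
        with pytest.raises(ScoringError):
            correctness_pvalue_exact(2, 1, 2, 1, 6, 4)

    def test_against_exhaustive_enumeration(self):
        expected = correctness_tail_by_enumeration(2, 1, 2, 1, 6, 2)
        assert correctness_pvalue_exact(2, 1, 2, 1, 6, 2) == pytest.approx(
            expected, rel=1e-12
        )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_randomized_grid_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(1, 9))
        q_plus = int(rng.integers(0, N + 1))
        q_minus = int(rng.integers(0, N - q_plus + 1))
        m_plus = int(rng.integers(0, N + 1))
        m_minus = int(rng.integers(0, N - m_plus + 1))
        s_obs = int(rng.integers(-(q_plus + q_minus), q_plus + q_minus + 1)) \
            if q_plus + q_minus else 0
        expected = correctness_tail_by_enumeration(
            q_plus, q_minus, m_plus, m_minus, N, s_obs
        )
        got = correctness_pvalue_exact(q_plus, q_minus, m_plus, m_minus, N, s_obs)
        assert got == pytest.approx(max(expected, 5e-324), rel=1e-9, abs=1e-12)


class TestCorrectnessMC:
    def test_recovers_known_half(self):
        p, se = correctness_pvalue_mc(1, 0, 1, 0, 2, 1, n_perm=10_000, seed=0)
        assert abs(p - 0.5) < 3 * se

    def test_deterministic_under_seed(self):
        args = (3, 2, 4, 3, 20, 2)
        assert correctness_pvalue_mc(*args, n_perm=500, seed=42) == \
            correctness_pvalue_mc(*args, n_perm=500, seed=42)

    def test_requires_minimum_permutations(self):
        with pytest.raises(ScoringError):
            correctness_pvalue_mc(1, 0, 1, 0, 2, 1, n_perm=50)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_within_three_stderr_of_exact(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(2, 9))
        q_plus = int(rng.integers(1, N + 1))
        q_minus = int(rng.integers(0, N - q_plus + 1))
        m_plus = int(rng.integers(1, N + 1))
        m_minus = int(rng.integers(0, N - m_plus + 1))
        s_obs = int(rng.integers(0, q_plus + q_minus + 1))
        exact = correctness_pvalue_exact(q_plus, q_minus, m_plus, m_minus, N, s_obs)
        p, se = correctness_pvalue_mc(
            q_plus, q_minus, m_plus, m_minus, N, s_obs, n_perm=4000, seed=seed
        )
        assert abs(p - exact) <= 3 * max(se, 1 / 4001)


class TestScoreAll:
    def test_both_signs_of_each_entity(self, chain_graph):
        profile = DEProfile(frozenset({"t1", "t2"}), {"t1": -1, "t2": 1})
        results = score_all_hypotheses(chain_graph, profile)
        labels = {r.label for r in results}
        assert labels == {"u+", "u-", "a+", "a-"}

    def test_empty_transcript_overlap_rejected(self, chain_graph):
        profile = DEProfile(frozenset({"x"}), {})
        with pytest.raises(ScoringError):
            score_all_hypotheses(chain_graph, profile)

    def test_negated_profile_swaps_signed_results(self):
        rng = np.random.default_rng(5)
        graph = random_graph(rng, n_nodes=10, n_transcripts=4, n_edges=16)
        profile = random_profile(rng, sorted(graph.transcript_nodes))
        fwd = score_all_hypotheses(graph, profile, seed=11)
        rev = score_all_hypotheses(graph, profile.negated(), seed=11)
        by_label = {r.label: r for r in rev}
        for r in fwd:
            mirror = by_label[r.hypothesis.entity +
                              ("-" if r.hypothesis.sign == 1 else "+")]
            assert (r.score, r.enrichment_p, r.correctness_p) == (
                mirror.score, mirror.enrichment_p, mirror.correctness_p
            )
            assert (r.q_plus, r.q_minus) == (mirror.q_minus, mirror.q_plus)
            assert (r.n_correct, r.n_incorrect) == (
                mirror.n_correct, mirror.n_incorrect
            )


    def test_all_zero_profile_gives_zero_scores(self, chain_graph):
        profile = DEProfile(frozenset({"t1", "t2"}), {})
        results = rank_and_filter(score_all_hypotheses(chain_graph, profile))
        assert all(r.score == 0 for r in results)
        assert not any(r.significant for r in results)
        assert all(r.enrichment_p == 1.0 for r in results)

    def test_growing_universe_with_inert_gene_is_benign(self):
        """An extra unchanged, unpredicted gene never adds outcomes and only
        nudges the p-values."""
        rng = np.random.default_rng(8)
        graph = random_graph(rng, n_nodes=10, n_transcripts=4, n_edges=16)
        universe = sorted(graph.transcript_nodes)
        profile = random_profile(rng, universe)
        bigger = DEProfile(frozenset(universe) | {"inert"}, dict(profile.calls))
        small = {r.label: r for r in score_all_hypotheses(graph, profile)}
        grown = {r.label: r for r in score_all_hypotheses(graph, bigger)}
        for label, r in small.items():
            g = grown[label]
            assert (g.n_correct, g.n_incorrect) == (r.n_correct, r.n_incorrect)
            # the same hits among more genes can only look rarer
            assert g.enrichment_p <= r.enrichment_p + 1e-12
            assert abs(g.correctness_p - r.correctness_p) < 0.5


class TestRankAndFilter:
    def test_distinct_scores_rank_in_order(self):
        results = [
            make_result("a", 1, 1, 1, 0.5, 0.5),
            make_result("b", 1, 5, 5, 0.5, 0.5),
            make_result("c", 1, 3, 3, 0.5, 0.5),
        ]
        ranked = rank_and_filter(results)
        assert [r.label for r in ranked] == ["b+", "c+", "a+"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_two_supporting_genes_never_significant(self):
        results = [make_result("a", 1, 2, 2, 1e-6, 1e-6)]
        assert not rank_and_filter(results)[0].significant

    def test_three_genes_and_marginal_pvalues_significant(self):
        results = [make_result("a", 1, 3, 3, 0.009, 0.009)]
        assert rank_and_filter(results)[0].significant

    def test_score_ties_broken_by_enrichment(self):
        results = [
            make_result("worse", 1, 3, 3, 0.005, 0.001),
            make_result("better", 1, 3, 3, 0.001, 0.005),
        ]
        ranked = rank_and_filter(results)
        assert [r.label for r in ranked] == ["better+", "worse+"]

    def test_rank_cutoff_excludes_deep_hypotheses(self):
        results = [
            make_result(f"filler{i:02d}", 1, 100 - i, 100 - i, 1e-6, 1e-6)
            for i in range(40)
        ]
        ranked = rank_and_filter(results)
        assert ranked[34].significant and not ranked[35].significant
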