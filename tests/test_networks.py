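import numpy as np
import pytest

from crengine import (
    CausalGraph,
    CausalStatement,
    DEProfile,
    Hypothesis,
    average_linkage_clusters,
    cosine_similarity,
    explanation_vectors,
    load_gmt,
    map_processes,
    prune_redundant,
    rank_and_filter,
    score_all_hypotheses,
)
from crengine.networks import (
    ExplanationVector,
    HypothesisCluster,
    NetworkError,
    similarity_graph,
    write_sif,
)

from test_scoring import make_result


def vec(label_entity, sign, entries):
    return ExplanationVector(Hypothesis(label_entity, sign), entries)


@pytest.fixture
def scored_setup():
    """Two regulators sharing targets plus one with disjoint targets."""
    statements = []
    for t in ("t1", "t2", "t3", "t4"):
        statements.append(CausalStatement("r1", 1, t, "transcript"))
    for t in ("t1", "t2", "t3"):
        statements.append(CausalStatement("r2", 1, t, "transcript"))
    for t in ("t5", "t6", "t7"):
        statements.append(CausalStatement("r3", -1, t, "transcript"))
    graph = CausalGraph(statements)
    universe = {f"t{i}" for i in range(1, 11)}
    profile = DEProfile(
        frozenset(universe),
        {"t1": 1, "t2": 1, "t3": 1, "t4": 1, "t5": -1, "t6": -1, "t7": -1},
    )
    # the toy universe is too small for the production p cutoff; relax it
    results = rank_and_filter(
        score_all_hypotheses(graph, profile, depth=1), p_cut=0.5
    )
    return graph, profile, results


class TestExplanationVectors:
    def test_one_entry_per_correct_gene(self, scored_setup):
        graph, profile, results = scored_setup
        vectors = explanation_vectors(results, graph, profile, depth=1)
        by_label = {v.label: v for v in vectors}
        assert by_label["r1+"].entries == {"t1": 1, "t2": 1, "t3": 1, "t4": 1}
        assert by_label["r3+"].entries == {"t5": -1, "t6": -1, "t7": -1}

    def test_only_significant_hypotheses_kept(self, scored_setup):
        graph, profile, results = scored_setup
        vectors = explanation_vectors(results, graph, profile, depth=1)
        assert {v.label for v in vectors} <= {
            r.label for r in results if r.significant
        }


class TestCosine:
    def test_identical_vectors(self):
        a = vec("a", 1, {"g1": 1, "g2": -1})
        assert cosine_similarity(a, a) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = vec("a", 1, {"g1": 1})
        b = vec("b", 1, {"g2": 1})
        assert cosine_similarity(a, b) == 0.0

    def test_orthogonal_signs(self):
        a = vec("a", 1, {"g1": 1, "g2": 1})
        b = vec("b", 1, {"g1": 1, "g2": -1})
        assert cosine_similarity(a, b) == 0.0

    def test_symmetry_and_empty_error(self):
        a = vec("a", 1, {"g1": 1, "g2": 1})
        b = vec("b", 1, {"g2": 1, "g3": -1})
        assert cosine_similarity(a, b) == cosine_similarity(b, a)
        with pytest.raises(NetworkError):
            cosine_similarity(a, vec("c", 1, {}))


class TestClustering:
    def make_results(self, labels):
        results = []
        for i, (entity, sign) in enumerate(labels):
            results.append(make_result(entity, sign, 10 - i, 10 - i, 1e-6, 1e-6))
        return rank_and_filter(results)

    def test_identical_vectors_merge(self):
        vectors = [vec("a", 1, {"g1": 1}), vec("b", 1, {"g1": 1})]
        results = self.make_results([("a", 1), ("b", 1)])
        clusters = average_linkage_clusters(vectors, results, 0.5)
        assert len(clusters) == 1 and clusters[0].members == {"a+", "b+"}

    def test_orthogonal_vectors_stay_apart(self):
        vectors = [vec("a", 1, {"g1": 1}), vec("b", 1, {"g2": 1})]
        results = self.make_results([("a", 1), ("b", 1)])
        clusters = average_linkage_clusters(vectors, results, 0.5)
        assert sorted(len(c.members) for c in clusters) == [1, 1]

    def test_mixed_pair_and_singleton(self):
        vectors = [
            vec("a", 1, {"g1": 1, "g2": 1}),
            vec("b", 1, {"g1": 1, "g2": 1}),
            vec("c", 1, {"g3": -1}),
        ]
        results = self.make_results([("a", 1), ("b", 1), ("c", 1)])
        clusters = average_linkage_clusters(vectors, results, 0.5)
        assert sorted(len(c.members) for c in clusters) == [1, 2]

    def test_partition_invariant_to_input_order(self):
        rng = np.random.default_rng(7)
        vectors = []
        for i in range(12):
            entries = {
                f"g{j}": int(rng.choice([-1, 1]))
                for j in rng.choice(20, size=rng.integers(2, 6), replace=False)
            }
            vectors.append(vec(f"h{i:02d}", 1, entries))
        results = self.make_results([(f"h{i:02d}", 1) for i in range(12)])
        ref = average_linkage_clusters(vectors, results, 0.7)
        ref_partition = sorted(tuple(sorted(c.members)) for c in ref)
        for _ in range(3):
            rng.shuffle(vectors)
            got = average_linkage_clusters(vectors, results, 0.7)
            assert sorted(tuple(sorted(c.members)) for c in got) == ref_partition

    def test_top_network_flag(self):
        cluster = HypothesisCluster({"a+", "b+", "c+"}, top_rank=10)
        assert cluster.is_top_network
        assert not HypothesisCluster({"a+", "b+"}, top_rank=1).is_top_network
        assert not HypothesisCluster({"a+", "b+", "c+"}, 30).is_top_network


class TestPruning:
    def setup_cluster(self, specs):
        """specs: list of (entity, score, genes); rank follows score order."""
        results = rank_and_filter(
            [make_result(e, 1, s, s, 1e-6, 1e-6) for e, s, _ in specs]
        )
        vectors = [
            vec(e, 1, {g: 1 for g in genes}) for e, _, genes in specs
        ]
        cluster = HypothesisCluster(
            {f"{e}+" for e, _, _ in specs},
            min(r.rank for r in results),
        )
        return cluster, results, vectors

    def test_subset_with_lower_score_removed_as_surrogate(self):
        cluster, results, vectors = self.setup_cluster(
            [("big", 3, {"g1", "g2", "g3"}), ("small", 2, {"g1", "g2"})]
        )
        reduced, log = prune_redundant(cluster, results, vectors, 0.9)
        assert reduced.members == {"big+"}
        assert log[0]["rule"] == "surrogate"

    def test_identical_sets_keep_better_rank(self):
        cluster, results, vectors = self.setup_cluster(
            [("first", 5, {"g1", "g2"}), ("second", 3, {"g1", "g2"})]
        )
        reduced, log = prune_redundant(cluster, results, vectors, 0.9)
        assert reduced.members == {"first+"}

    def test_disjoint_sets_untouched(self):
        cluster, results, vectors = self.setup_cluster(
            [("a", 4, {"g1"}), ("b", 3, {"g2"})]
        )
        reduced, log = prune_redundant(cluster, results, vectors, 0.9)
        assert reduced.members == {"a+", "b+"} and log == []

    def test_best_ranked_member_never_removed(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            specs = [
                (f"e{i}", int(rng.integers(1, 6)),
                 {f"g{j}" for j in rng.choice(6, rng.integers(1, 5),
                                              replace=False)})
                for i in range(5)
            ]
            cluster, results, vectors = self.setup_cluster(specs)
            best = min(cluster.members,
                       key=lambda m: next(r.rank for r in results
                                          if r.label == m))
            reduced, _ = prune_redundant(cluster, results, vectors, 0.6)
            assert best in reduced.members


class TestProcessMapping:
    def test_single_up_member(self):
        results = rank_and_filter([make_result("u", 1, 5, 5, 1e-6, 1e-6)])
        calls = map_processes(results, {"proc": {"u"}})
        assert len(calls) == 1
        assert (calls[0].direction, calls[0].support) == ("UP", 5)

    def test_balanced_members_are_mixed(self):
        results = rank_and_filter(
            [
                make_result("a", 1, 5, 5, 1e-6, 1e-6),
                make_result("b", -1, 5, 5, 1e-6, 1e-6),
            ]
        )
        calls = map_processes(results, {"proc": {"a", "b"}})
        assert calls[0].direction == "MIXED" and calls[0].net == 0

    def test_unannotated_processes_omitted(self):
        results = rank_and_filter([make_result("u", 1, 5, 5, 1e-6, 1e-6)])
        calls = map_processes(results, {"proc": {"other"}, "hit": {"u"}})
        assert [c.process for c in calls] == ["hit"]

    def test_empty_annotations_rejected(self):
        with pytest.raises(NetworkError):
            map_processes([], {})

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "ann.gmt"
        path.write_text("p1\tdesc\te1\te2\np2\tdesc\te3\n")
        assert load_gmt(path) == {"p1": {"e1", "e2"}, "p2": {"e3"}}
        (tmp_path / "bad.gmt").write_text("p1\tdesc\n")
        with pytest.raises(NetworkError):
            load_gmt(tmp_path / "bad.gmt")


def test_similarity_exports(tmp_path):
    vectors = [
        vec("a", 1, {"g1": 1, "g2": 1}),
        vec("b", 1, {"g1": 1, "g2": 1}),
        vec("c", 1, {"g9": -1}),
    ]
    g = similarity_graph(vectors, min_similarity=0.4)
    assert g.has_edge("a+", "b+") and not g.has_edge("a+", "c+")
    sif = tmp_path / "net.sif"
    write_sif(vectors, sif)
    lines = sif.read_text().splitlines()
    assert "a+\tsimilar_to\tb+" in lines and "c+" in lines
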