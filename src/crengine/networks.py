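"""Network summarisation of significant hypotheses.

Significant hypotheses are grouped by the evidence they explain: each one is
reduced to a signed *explanation vector* over the genes it correctly explains,
pairwise cosine similarity on those vectors feeds average-linkage agglomerative
clustering, and each cluster is pruned of redundant and surrogate hypotheses.
A cluster qualifies as a *top network* when it has at least 3 members, one of
which ranks in the top 25 hypotheses.  Clusters are finally mapped onto
biological processes through a GMT-style annotation table, yielding per-process
direction calls (UP / DOWN / MIXED) for the cross-condition heatmap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .de_profiles import DEProfile
from .knowledgebase import CausalGraph, downstream_predictions
from .scoring import Hypothesis, HypothesisResult

logger = logging.getLogger(__name__)

DEFAULT_CUT_DISTANCE = 0.6
DEFAULT_JACCARD = 0.9
# a surrogate's explained genes may include the odd coincidental background
# gene; requiring only 3/4 containment keeps the call stable under noise
DEFAULT_CONTAINMENT = 0.75
DEFAULT_DOMINANCE = 0.33

UP, DOWN, MIXED = "UP", "DOWN", "MIXED"


class NetworkError(ValueError):
    pass


@dataclass
class ExplanationVector:
    """Signed indicator of the genes a hypothesis correctly explains."""

    hypothesis: Hypothesis
    entries: dict[str, int]

    @property
    def label(self) -> str:
        return self.hypothesis.label

    @property
    def genes(self) -> set[str]:
        return set(self.entries)


@dataclass
class HypothesisCluster:
    members: set[str]  # hypothesis labels
    top_rank: int

    @property
    def is_top_network(self) -> bool:
        return len(self.members) >= 3 and self.top_rank <= 25


@dataclass
class ProcessCall:
    process: str
    direction: str
    member_hypotheses: set[str]
    support: int
    net: int
    backed_by_top_network: bool = False


def explanation_vectors(
    results: list[HypothesisResult],
    graph: CausalGraph,
    profile: DEProfile,
    depth: int = 2,
    traverse_transcripts: bool = False,
) -> list[ExplanationVector]:
    """One vector per significant hypothesis over its correctly explained genes.

    Hypotheses explaining nothing correctly are dropped with a warning.
    """
    vectors = []
    for r in results:
        if not r.significant:
            continue
        pred = downstream_predictions(
            graph, r.hypothesis.entity, r.hypothesis.sign, depth,
            traverse_transcripts,
        )
        entries = {
            t: s
            for t, s in pred.signed_items().items()
            if t in profile.universe and profile.call(t) == s
        }
        if not entries:
            logger.warning(
                "significant hypothesis %s explains no gene correctly; dropped",
                r.label,
            )
            continue
        vectors.append(ExplanationVector(r.hypothesis, entries))
    return vectors


def cosine_similarity(a: ExplanationVector, b: ExplanationVector) -> float:
    """Cosine of the two signed vectors over the union of their genes."""
    if not a.entries or not b.entries:
        raise NetworkError("cosine similarity is undefined for an empty vector")
    dot = sum(s * b.entries.get(g, 0) for g, s in a.entries.items())
    return dot / math.sqrt(len(a.entries) * len(b.entries))


def _rank_of(label: str, results: list[HypothesisResult]) -> int:
    for r in results:
        if r.label == label and r.rank is not None:
            return r.rank
    return np.iinfo(np.int32).max


def average_linkage_clusters(
    vectors: list[ExplanationVector],
    results: list[HypothesisResult],
    cut_distance: float = DEFAULT_CUT_DISTANCE,
) -> list[HypothesisCluster]:
    """Agglomerative average-linkage clustering on cosine distance (1 - cos).

    The dendrogram is cut at ``cut_distance``.  Vectors are processed in
    lexicographic label order, which makes merge order — and hence the
    partition — independent of input order.
    """
    if not vectors:
        raise NetworkError("need at least one explanation vector")
    if not 0 <= cut_distance <= 2:
        raise NetworkError(f"cut_distance must lie in [0, 2], got {cut_distance}")
    vectors = sorted(vectors, key=lambda v: v.label)
    if len(vectors) == 1:
        labels = np.ones(1, dtype=int)
    else:
        genes = sorted(set().union(*(v.genes for v in vectors)))
        idx = {g: i for i, g in enumerate(genes)}
        X = np.zeros((len(vectors), len(genes)))
        for i, v in enumerate(vectors):
            for g, s in v.entries.items():
                X[i, idx[g]] = s
        Z = linkage(pdist(X, metric="cosine"), method="average")
        labels = fcluster(Z, t=cut_distance, criterion="distance")
    clusters: dict[int, set[str]] = {}
    for v, lab in zip(vectors, labels):
        clusters.setdefault(int(lab), set()).add(v.label)
    out = [
        HypothesisCluster(members, min(_rank_of(m, results) for m in members))
        for members in clusters.values()
    ]
    out.sort(key=lambda c: (c.top_rank, sorted(c.members)))
    return out


def prune_redundant(
    cluster: HypothesisCluster,
    results: list[HypothesisResult],
    vectors: list[ExplanationVector],
    jaccard_threshold: float = DEFAULT_JACCARD,
    surrogate_containment: float = DEFAULT_CONTAINMENT,
) -> tuple[HypothesisCluster, list[dict]]:
    """Remove surrogate and redundant members from a cluster.

    Walking members from best to worst rank, a member is removed when a
    better-ranked kept member either (a) *surrogate rule*: correctly explains
    at least ``surrogate_containment`` of its genes with greater-or-equal
    score (an exact superset when the threshold is 1; the tolerance absorbs
    the odd coincidental background gene), or (b) *redundancy rule*: overlaps
    it with Jaccard index at least ``jaccard_threshold``.  The best-ranked
    member is therefore never removed.  Returns the reduced cluster and a
    removal log.
    """
    if not 0 <= jaccard_threshold <= 1:
        raise NetworkError("jaccard_threshold must lie in [0, 1]")
    if not 0 < surrogate_containment <= 1:
        raise NetworkError("surrogate_containment must lie in (0, 1]")
    by_label = {r.label: r for r in results}
    vec_by_label = {v.label: v for v in vectors}
    ordered = sorted(cluster.members, key=lambda m: _rank_of(m, results))
    kept: list[str] = []
    removals: list[dict] = []
    for member in ordered:
        genes = vec_by_label[member].genes if member in vec_by_label else set()
        score = by_label[member].score if member in by_label else 0
        fired = None
        for keeper in kept:
            kgenes = vec_by_label[keeper].genes if keeper in vec_by_label else set()
            kscore = by_label[keeper].score if keeper in by_label else 0
            if (
                genes
                and len(genes & kgenes) / len(genes) >= surrogate_containment
                and score <= kscore
            ):
                fired = ("surrogate", keeper)
                break
            union = genes | kgenes
            if union and len(genes & kgenes) / len(union) >= jaccard_threshold:
                fired = ("redundant", keeper)
                break
        if fired is None:
            kept.append(member)
        else:
            removals.append(
                {"removed": member, "rule": fired[0], "kept": fired[1]}
            )
            logger.info(
                "pruned %s (%s of %s)", member, fired[0], fired[1]
            )
    reduced = HypothesisCluster(set(kept), min(_rank_of(m, results) for m in kept))
    return reduced, removals


def eliminate_redundant_hypotheses(
    results: list[HypothesisResult],
    vectors: list[ExplanationVector],
    jaccard_threshold: float = DEFAULT_JACCARD,
    surrogate_containment: float = DEFAULT_CONTAINMENT,
) -> tuple[list[HypothesisResult], list[dict]]:
    """Apply the surrogate/redundancy elimination across the whole significant
    set (rather than within one cluster).

    This is the step used before summarising hypotheses at the process level:
    a hypothesis whose explained evidence is (almost) wholly contained in a
    stronger hypothesis's adds no process of its own, whichever display
    cluster it falls into.  Returns the surviving significant results and the
    removal log.
    """
    labels = {v.label for v in vectors} & {
        r.label for r in results if r.significant
    }
    if not labels:
        return [], []
    whole = HypothesisCluster(labels, min(_rank_of(m, results) for m in labels))
    reduced, removals = prune_redundant(
        whole, results, vectors, jaccard_threshold, surrogate_containment
    )
    kept = [r for r in results if r.significant and r.label in reduced.members]
    return kept, removals


# -- process mapping ---------------------------------------------------------

def load_gmt(path) -> dict[str, set[str]]:
    """Read a GMT annotation table: ``process  description  entity...``."""
    annotations: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NetworkError(
                    f"{path}: line {lineno}: GMT rows need process, "
                    "description and at least one entity"
                )
            annotations[fields[0]] = {f for f in fields[2:] if f}
    if not annotations:
        raise NetworkError(f"{path}: empty annotation table")
    return annotations


def map_processes(
    results: list[HypothesisResult],
    annotations: dict[str, set[str]],
    clusters: list[HypothesisCluster] | None = None,
    dominance_threshold: float = DEFAULT_DOMINANCE,
) -> list[ProcessCall]:
    """Summarise significant hypotheses at the biological-process level.

    For each process, the members are the significant hypotheses whose entity
    is annotated to it.  The net signed support is the sum of
    ``sign(h) * score(h)`` over members; the call is UP (DOWN) when the net is
    positive (negative) and its dominance ``|net| / sum(|score|)`` reaches the
    threshold, MIXED otherwise.  Processes with no member are omitted.  When
    ``clusters`` are supplied, each call also records whether any member
    belongs to a top-ranking network.
    """
    if not annotations:
        raise NetworkError("empty annotation table")
    significant = [r for r in results if r.significant]
    top_members: set[str] = set()
    if clusters:
        for c in clusters:
            if c.is_top_network:
                top_members |= c.members
    calls = []
    for process in sorted(annotations):
        entities = annotations[process]
        members = [r for r in significant if r.hypothesis.entity in entities]
        if not members:
            continue
        net = sum(r.hypothesis.sign * r.score for r in members)
        total = sum(abs(r.score) for r in members)
        dominance = abs(net) / total if total else 0.0
        if net > 0 and dominance >= dominance_threshold:
            direction = UP
        elif net < 0 and dominance >= dominance_threshold:
            direction = DOWN
        else:
            direction = MIXED
        calls.append(
            ProcessCall(
                process,
                direction,
                {r.label for r in members},
                total,
                net,
                bool(top_members & {r.label for r in members}),
            )
        )
    return calls


# -- exports -----------------------------------------------------------------

def similarity_graph(vectors: list[ExplanationVector], min_similarity: float = 0.4):
    """Hypothesis–hypothesis cosine-similarity graph as a networkx Graph."""
    import networkx as nx

    g = nx.Graph()
    for v in vectors:
        g.add_node(v.label, n_explained=len(v.entries))
    for i, a in enumerate(vectors):
        for b in vectors[i + 1:]:
            sim = cosine_similarity(a, b)
            if sim >= min_similarity:
                g.add_edge(a.label, b.label, similarity=round(sim, 6))
    return g


def write_graphml(vectors: list[ExplanationVector], path, min_similarity: float = 0.4):
    import networkx as nx

    nx.write_graphml(similarity_graph(vectors, min_similarity), path)


def write_sif(vectors: list[ExplanationVector], path, min_similarity: float = 0.4):
    """Cytoscape SIF export (``a  similar_to  b`` per retained edge)."""
    g = similarity_graph(vectors, min_similarity)
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(g.edges):
            fh.write(f"{a}\tsimilar_to\t{b}\n")
        for node in sorted(g.nodes):
            if g.degree(node) == 0:
                fh.write(f"{node}\n")
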