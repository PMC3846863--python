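"""Signed causal knowledgebase: statements, graph, and downstream sign propagation.

The knowledgebase is a collection of curated, signed, directed statements
``A increases B`` / ``A decreases B`` between molecular entities (protein
activities, compounds, processes, transcript levels).  Transcript-level nodes
form the measurement layer: a *hypothesis* — an entity together with an assumed
direction of activity change — predicts a sign for every transcript node it can
reach, and those predictions are what get compared against an observed
differential-expression profile.

Sign propagation uses walk semantics: every directed walk of length at most
``depth`` contributes the product of its edge signs (times the hypothesis
sign); a transcript reachable with both net signs is AMBIGUOUS.  Transcript
nodes are terminal for traversal by default, because they represent measured
mRNA levels rather than regulatory activities.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

LAYERS = ("transcript", "activity", "compound", "process")
TRANSCRIPT = "transcript"

#: Sentinel marking a transcript reachable with both net signs.
AMBIGUOUS = "ambiguous"

_SIGN_TOKENS = {"increases": 1, "decreases": -1, "+1": 1, "-1": -1, "−1": -1}
_SIGN_NAMES = {1: "increases", -1: "decreases"}


class KnowledgebaseError(ValueError):
    """Raised for malformed knowledgebase files or invalid graph queries."""


@dataclass(frozen=True)
class CausalStatement:
    """One signed, directed causal edge: ``source`` increases/decreases ``target``."""

    source: str
    sign: int
    target: str
    target_layer: str
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise KnowledgebaseError(f"statement sign must be +1 or -1, got {self.sign!r}")
        if self.target_layer not in LAYERS:
            raise KnowledgebaseError(
                f"unknown target layer {self.target_layer!r}; expected one of {LAYERS}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.source, self.sign, self.target)


class CausalGraph:
    """A validated signed causal graph with duplicate statements collapsed.

    Duplicate ``(source, sign, target)`` triples are merged (evidence lists
    concatenated).  A pair ``(A, +1, B)`` and ``(A, -1, B)`` — contradictory
    literature — is retained as two edges and propagates as AMBIGUOUS through
    any walk that uses either of them.
    """

    def __init__(self, statements: Iterable[CausalStatement]):
        merged: dict[tuple[str, int, str], CausalStatement] = {}
        layers: dict[str, str] = {}
        for st in statements:
            source = st.source.strip()
            target = st.target.strip()
            if not source or not target:
                raise KnowledgebaseError("empty entity identifier in statement")
            st = CausalStatement(source, st.sign, target, st.target_layer, st.evidence)
            prev_layer = layers.get(target)
            if prev_layer is not None and prev_layer != st.target_layer:
                raise KnowledgebaseError(
                    f"entity {target!r} appears with conflicting layers "
                    f"{prev_layer!r} and {st.target_layer!r}"
                )
            layers[target] = st.target_layer
            if st.key in merged:
                old = merged[st.key]
                merged[st.key] = CausalStatement(
                    st.source, st.sign, st.target, st.target_layer,
                    old.evidence + st.evidence,
                )
            else:
                merged[st.key] = st
        if not merged:
            raise KnowledgebaseError("knowledgebase contains no statements")

        self._statements = merged
        self._layers = layers
        self.entities: set[str] = set()
        self._adjacency: dict[str, list[tuple[str, int]]] = {}
        for (source, sign, target) in merged:
            self.entities.add(source)
            self.entities.add(target)
            self._adjacency.setdefault(source, []).append((target, sign))
        # deterministic expansion order
        for targets in self._adjacency.values():
            targets.sort()

    # -- introspection -------------------------------------------------------

    @property
    def statements(self) -> list[CausalStatement]:
        return [self._statements[k] for k in sorted(self._statements)]

    @property
    def transcript_nodes(self) -> set[str]:
        return {e for e, layer in self._layers.items() if layer == TRANSCRIPT}

    def layer_of(self, entity: str) -> str | None:
        """Layer of ``entity`` when it occurs as a target; None for pure sources."""
        return self._layers.get(entity)

    def is_transcript(self, entity: str) -> bool:
        return self._layers.get(entity) == TRANSCRIPT

    def out_edges(self, entity: str) -> list[tuple[str, int]]:
        return self._adjacency.get(entity, [])

    def non_transcript_entities(self) -> list[str]:
        return sorted(e for e in self.entities if not self.is_transcript(e))

    def contradictory_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for (source, sign, target) in self._statements:
            if sign == 1 and (source, -1, target) in self._statements:
                pairs.append((source, target))
        return pairs

    def self_loops(self) -> list[tuple[str, int, str]]:
        return [k for k in self._statements if k[0] == k[2]]

    def validation_report(self) -> dict[str, int]:
        report = {
            "n_statements": len(self._statements),
            "n_entities": len(self.entities),
            "n_transcript_nodes": len(self.transcript_nodes),
            "n_contradictory_pairs": len(self.contradictory_pairs()),
            "n_self_loops": len(self.self_loops()),
        }
        logger.info("knowledgebase: %s", report)
        return report

    def __len__(self) -> int:
        return len(self._statements)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalGraph):
            return NotImplemented
        return set(self._statements) == set(other._statements)

    def to_networkx(self):
        """Export as a :class:`networkx.MultiDiGraph` (sign and layer attributes)."""
        import networkx as nx

        g = nx.MultiDiGraph()
        for e in self.entities:
            g.add_node(e, layer=self._layers.get(e, "source-only"))
        for st in self.statements:
            g.add_edge(st.source, st.target, sign=st.sign,
                       evidence=";".join(st.evidence))
        return g


@dataclass
class PredictionSet:
    """Signed transcript-level predictions of one hypothesis.

    ``predictions`` maps each transcript node reachable within ``depth``
    directed edges to +1, -1 or :data:`AMBIGUOUS`.
    """

    hypothesis_entity: str
    hypothesis_sign: int
    predictions: dict[str, object]
    depth: int

    def signed_items(self) -> dict[str, int]:
        return {t: s for t, s in self.predictions.items() if s is not AMBIGUOUS}

    def ambiguous_nodes(self) -> set[str]:
        return {t for t, s in self.predictions.items() if s is AMBIGUOUS}

    def negated(self) -> "PredictionSet":
        flipped = {
            t: (s if s is AMBIGUOUS else -s) for t, s in self.predictions.items()
        }
        return PredictionSet(
            self.hypothesis_entity, -self.hypothesis_sign, flipped, self.depth
        )


def downstream_predictions(
    graph: CausalGraph,
    entity: str,
    sign: int,
    depth: int = 2,
    traverse_transcripts: bool = False,
) -> PredictionSet:
    """All transcript-level sign predictions of hypothesis ``(entity, sign)``.

    Performs a breadth-first search over (node, accumulated sign) states, which
    yields for every transcript node the set of net signs attainable by some
    directed walk of length 1..``depth``.  Transcript nodes are not expanded
    unless ``traverse_transcripts`` is set (the start node is always expanded).
    """
    if entity not in graph.entities:
        raise KnowledgebaseError(f"unknown entity {entity!r}")
    if sign not in (1, -1):
        raise KnowledgebaseError(f"hypothesis sign must be +1 or -1, got {sign!r}")
    if depth < 1:
        raise KnowledgebaseError(f"depth must be >= 1, got {depth}")

    seen: set[tuple[str, int]] = {(entity, sign)}
    frontier: deque[tuple[str, int, int]] = deque([(entity, sign, 0)])
    reached: dict[str, set[int]] = {}
    while frontier:
        node, acc, d = frontier.popleft()
        if d >= depth:
            continue
        if d > 0 and graph.is_transcript(node) and not traverse_transcripts:
            continue
        for target, edge_sign in graph.out_edges(node):
            state = (target, acc * edge_sign)
            if state in seen:
                continue
            seen.add(state)
            if graph.is_transcript(target):
                reached.setdefault(target, set()).add(state[1])
            frontier.append((target, state[1], d + 1))

    predictions: dict[str, object] = {}
    for t, signs in reached.items():
        predictions[t] = signs.pop() if len(signs) == 1 else AMBIGUOUS
    return PredictionSet(entity, sign, predictions, depth)


# -- TSV dialect -------------------------------------------------------------

_COLUMNS = ("source_id", "sign", "target_id", "target_layer", "evidence")


def load_knowledgebase(path) -> CausalGraph:
    """Read a knowledgebase TSV (columns ``source_id  sign  target_id
    target_layer  evidence``; ``#`` comment lines; UTF-8) into a validated
    :class:`CausalGraph`.  Malformed rows raise with their line number."""
    statements: list[CausalStatement] = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields[:4]] != list(_COLUMNS[:4]):
                    raise KnowledgebaseError(
                        f"{path}: line {lineno}: expected header {_COLUMNS}"
                    )
                header_seen = True
                continue
            if len(fields) not in (4, 5):
                raise KnowledgebaseError(
                    f"{path}: line {lineno}: expected 4 or 5 tab-separated "
                    f"columns, got {len(fields)}"
                )
            source, sign_token, target, layer = (f.strip() for f in fields[:4])
            evidence = fields[4].strip() if len(fields) == 5 else ""
            if sign_token not in _SIGN_TOKENS:
                raise KnowledgebaseError(
                    f"{path}: line {lineno}: sign token {sign_token!r} not in "
                    f"{sorted(set(_SIGN_TOKENS))}"
                )
            if layer not in LAYERS:
                raise KnowledgebaseError(
                    f"{path}: line {lineno}: unknown target layer {layer!r}"
                )
            statements.append(
                CausalStatement(
                    source, _SIGN_TOKENS[sign_token], target, layer,
                    tuple(e for e in evidence.split(";") if e),
                )
            )
    if not statements:
        raise KnowledgebaseError(f"{path}: no causal statements found")
    graph = CausalGraph(statements)
    graph.validation_report()
    return graph


def save_knowledgebase(graph: CausalGraph, path) -> None:
    """Write ``graph`` in the knowledgebase TSV dialect.

    ``load_knowledgebase(save_knowledgebase(g))`` round-trips the statement
    set exactly; merged evidence is written semicolon-joined.
    """
    if len(graph) == 0:  # CausalGraph refuses construction, but guard anyway
        raise KnowledgebaseError("refusing to write an empty knowledgebase")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for st in graph.statements:
            fh.write(
                "\t".join(
                    (
                        st.source,
                        _SIGN_NAMES[st.sign],
                        st.target,
                        st.target_layer,
                        ";".join(st.evidence),
                    )
                )
                + "\n"
            )
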