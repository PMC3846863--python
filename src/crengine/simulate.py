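"""Synthetic causal knowledgebases and planted-mechanism expression profiles.

The generator emulates the statistical structure that upstream-regulator
inference consumes, without any licensed content: a layered signed causal
graph (regulators -> intermediates -> transcript-level leaves), a small set of
planted active (regulator, direction) mechanisms whose signs propagate down
the graph, and a ternary observation process with sign-flip noise, dropout,
and symmetric background differential expression.  Paired "in vivo"/"in
vitro" conditions share a controllable fraction of their planted mechanisms,
which is what the translatability analysis is benchmarked against.

Identifiability is a design contract of the generator, not an accident:

* regulator out-degrees follow a variance-bounded (truncated) Poisson law;
* transcripts are partitioned near-evenly across intermediates (plus a small
  rate of second parents), so no single intermediate dominates the layer;
* regulator -> intermediate sets are sampled so that no *pair* of
  intermediates is co-regulated by two regulators (best effort, logged),
  which bounds how much of a planted mechanism's downstream evidence any
  decoy regulator can mimic;
* planted mechanisms are drawn among well-connected regulators (out-degree
  at least the configured mean) with mutually disjoint intermediate sets.

Under these conditions a zero-noise condition always ranks the planted
mechanisms above every decoy.  All outputs are bit-for-bit reproducible
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .de_profiles import DEProfile
from .knowledgebase import TRANSCRIPT, CausalGraph, CausalStatement
from .scoring import HypothesisResult

logger = logging.getLogger(__name__)

REG_PREFIX, MID_PREFIX, TX_PREFIX = "REG_", "MID_", "TX_"


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions of one simulated experiment.

    ``flip_noise`` is the probability that a truly changed transcript is
    observed with the opposite sign; ``dropout`` the probability it is not
    called at all; ``background_rate`` the probability an unaffected
    transcript is called changed (split evenly between directions unless
    ``background_up_bias`` is moved off 0.5).
    """

    n_regulators: int = 200
    n_intermediates: int = 100
    n_transcripts: int = 2000
    out_degree_mean: float = 6.0
    p_negative_edge: float = 0.25
    depth_layers: int = 2
    flip_noise: float = 0.1
    dropout: float = 0.1
    background_rate: float = 0.05
    n_planted: int = 3
    overlap_fraction: float = 0.5
    seed: int = 0
    # secondary knobs (defaults are part of the study conditions)
    reg_reg_rate: float = 0.05
    p_second_parent: float = 0.05
    background_up_bias: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_regulators", "n_intermediates", "n_transcripts"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        for name in (
            "p_negative_edge", "flip_noise", "dropout", "background_rate",
            "overlap_fraction", "reg_reg_rate", "p_second_parent",
            "background_up_bias",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")
        if self.out_degree_mean <= 0:
            raise SimulationError("out_degree_mean must be positive")
        if self.depth_layers not in (2, 3):
            raise SimulationError("depth_layers must be 2 or 3")
        if self.n_planted < 0:
            raise SimulationError("n_planted must be nonnegative")


REQUIRED_CONFIG_KEYS = (
    "n_regulators", "n_intermediates", "n_transcripts", "out_degree_mean",
    "p_negative_edge", "depth_layers", "flip_noise", "dropout",
    "background_rate", "n_planted", "overlap_fraction", "seed",
)


def load_config(path) -> SimulationConfig:
    """Read a flat YAML/JSON key-value file into a :class:`SimulationConfig`."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SimulationError(f"{path}: expected a flat key-value mapping")
    missing = [k for k in REQUIRED_CONFIG_KEYS if k not in raw]
    if missing:
        raise SimulationError(f"{path}: missing config key(s): {', '.join(missing)}")
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise SimulationError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated condition."""

    planted: list[tuple[str, int]]
    intended: dict[str, int]
    n_conflicting_transcripts: int
    n_flipped: int
    n_dropped: int
    n_background: int
    config: dict

    def to_json(self, path) -> None:
        payload = {
            "planted": [[e, s] for e, s in self.planted],
            "intended": self.intended,
            "n_conflicting_transcripts": self.n_conflicting_transcripts,
            "n_flipped": self.n_flipped,
            "n_dropped": self.n_dropped,
            "n_background": self.n_background,
            "config": self.config,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            [(e, int(s)) for e, s in payload["planted"]],
            {t: int(s) for t, s in payload["intended"].items()},
            payload["n_conflicting_transcripts"],
            payload["n_flipped"],
            payload["n_dropped"],
            payload["n_background"],
            payload["config"],
        )


# -- graph generation --------------------------------------------------------

def _truncated_poisson(rng, mean: float, size: int) -> np.ndarray:
    """Poisson draws clipped to [round(0.6*mean), max(.., round(1.5*mean))].

    Keeps the configured mean approximately while bounding the variance, so
    no layer node is starved of targets and no single node dominates a layer.
    """
    lo = max(1, int(round(0.6 * mean)))
    hi = max(lo + 1, int(round(1.5 * mean)))
    return np.clip(rng.poisson(mean, size=size), lo, hi)


def _names(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def regulator_names(config: SimulationConfig) -> list[str]:
    return _names(REG_PREFIX, config.n_regulators)


def _edge_sign(rng, p_negative: float) -> int:
    return -1 if rng.random() < p_negative else 1


def _pair_constrained_subsets(rng, pool: list[str], sizes, max_restarts=40):
    """Draw one subset of ``pool`` per requested size, avoiding any repeated
    unordered pair of elements across subsets (best effort).

    Element-wise greedy: each pick is uniform among the elements that do not
    recreate an already-used pair; a blocked draw restarts, and after
    ``max_restarts`` the least-colliding attempt is accepted (collisions are
    counted and logged).  Bounding pairwise subset overlap to one element
    keeps any two regulators' downstream programmes nearly distinct.
    """
    used_pairs: set[tuple[str, str]] = set()
    subsets: list[list[str]] = []
    collisions = 0
    for size in sizes:
        size = min(int(size), len(pool))
        best, best_bad = None, None
        for _ in range(max_restarts):
            chosen: list[str] = []
            bad = 0
            candidates = list(pool)
            rng.shuffle(candidates)
            for cand in candidates:
                conflicts = sum(
                    1 for c in chosen
                    if (min(c, cand), max(c, cand)) in used_pairs
                )
                if conflicts == 0:
                    chosen.append(cand)
                    if len(chosen) == size:
                        break
            if len(chosen) == size:
                best, best_bad = chosen, 0
                break
            # fill the remainder accepting collisions, remember the best
            for cand in candidates:
                if len(chosen) == size:
                    break
                if cand not in chosen:
                    bad += sum(
                        1 for c in chosen
                        if (min(c, cand), max(c, cand)) in used_pairs
                    )
                    chosen.append(cand)
            if best_bad is None or bad < best_bad:
                best, best_bad = chosen, bad
        collisions += best_bad or 0
        for i, x in enumerate(best):
            for y in best[i + 1:]:
                used_pairs.add((min(x, y), max(x, y)))
        subsets.append(sorted(best))
    if collisions:
        logger.info(
            "pair-constrained assignment reused %d intermediate pairs",
            collisions,
        )
    return subsets


def _partitioned_children(rng, parents: list[str], children: list[str],
                          p_second: float):
    """Assign every child one parent (balanced round-robin over a shuffled
    order) plus a second random parent at rate ``p_second``."""
    order = list(children)
    rng.shuffle(order)
    assignment: dict[str, list[str]] = {}
    for i, child in enumerate(order):
        parent_list = [parents[i % len(parents)]]
        if len(parents) > 1 and rng.random() < p_second:
            extra = parents[rng.integers(len(parents))]
            if extra not in parent_list:
                parent_list.append(extra)
        assignment[child] = parent_list
    return assignment


def generate_knowledgebase(config: SimulationConfig) -> CausalGraph:
    """Layered signed causal graph; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    regs = regulator_names(config)
    mids = _names(MID_PREFIX, config.n_intermediates)
    txs = _names(TX_PREFIX, config.n_transcripts)
    if config.depth_layers == 3:
        half = max(1, config.n_intermediates // 2)
        upper, lower = mids[:half], mids[half:] or mids[:half]
    else:
        upper = lower = mids

    statements: list[CausalStatement] = []
    degrees = _truncated_poisson(rng, config.out_degree_mean, len(regs))
    targets = _pair_constrained_subsets(rng, upper, degrees)
    for reg, reg_targets in zip(regs, targets):
        for mid in reg_targets:
            statements.append(
                CausalStatement(reg, _edge_sign(rng, config.p_negative_edge),
                                mid, "activity")
            )
        if len(regs) > 1 and rng.random() < config.reg_reg_rate:
            other = regs[rng.integers(len(regs))]
            if other != reg:
                statements.append(
                    CausalStatement(reg, _edge_sign(rng, config.p_negative_edge),
                                    other, "activity")
                )
    if config.depth_layers == 3:
        for mid, parents in sorted(
            _partitioned_children(rng, upper, lower, config.p_second_parent).items()
        ):
            for parent in parents:
                if parent != mid:
                    statements.append(
                        CausalStatement(parent,
                                        _edge_sign(rng, config.p_negative_edge),
                                        mid, "activity")
                    )
    for tx, parents in sorted(
        _partitioned_children(rng, lower, txs, config.p_second_parent).items()
    ):
        for parent in parents:
            statements.append(
                CausalStatement(parent, _edge_sign(rng, config.p_negative_edge),
                                tx, TRANSCRIPT)
            )
    return CausalGraph(statements)


# -- condition simulation ----------------------------------------------------

def _signed_adjacency(graph: CausalGraph):
    from scipy import sparse

    nodes = sorted(graph.entities)
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for st in graph.statements:
        rows.append(index[st.source])
        cols.append(index[st.target])
        vals.append(st.sign)
    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(nodes), len(nodes)), dtype=float
    )
    return A, nodes, index


def _mechanism_contributions(graph: CausalGraph, planted, depth: int):
    """Signed walk-count contribution of each planted mechanism per transcript."""
    A, nodes, index = _signed_adjacency(graph)
    tx_mask = np.array([graph.is_transcript(n) for n in nodes])
    contribs = []
    for entity, sign in planted:
        v = np.zeros(len(nodes))
        v[index[entity]] = float(sign)
        total = np.zeros(len(nodes))
        walk = v
        for _ in range(depth):
            walk = walk @ A
            total += walk
        contribs.append(total * tx_mask)
    return contribs, nodes, tx_mask


def intended_signs(
    graph: CausalGraph, planted: list[tuple[str, int]], depth: int
) -> tuple[dict[str, int], int]:
    """Per-transcript intended sign of the planted mechanism set.

    Each mechanism contributes the signed count of walks (length <= depth)
    from its regulator to the transcript; conflicts resolve by the sign of
    the summed contributions, with an exact zero meaning unchanged.  Returns
    the intended non-zero signs and the number of conflicting transcripts.
    """
    if not planted:
        return {}, 0
    contribs, nodes, _ = _mechanism_contributions(graph, planted, depth)
    stacked = np.vstack(contribs)
    total = stacked.sum(axis=0)
    conflict = (stacked > 0).any(axis=0) & (stacked < 0).any(axis=0)
    intended = {
        nodes[i]: int(np.sign(total[i]))
        for i in np.nonzero(total)[0]
    }
    n_conflicts = int(np.count_nonzero(conflict))
    if n_conflicts:
        logger.info(
            "%d transcripts receive conflicting planted contributions",
            n_conflicts,
        )
    return intended, n_conflicts


def _intermediate_targets(graph: CausalGraph, reg: str) -> frozenset:
    return frozenset(t for t, _ in graph.out_edges(reg)
                     if t.startswith(MID_PREFIX))


def _draw_planted(
    rng, config: SimulationConfig, graph: CausalGraph, exclude=()
) -> list[tuple[str, int]]:
    """Planted mechanisms: well-connected regulators with disjoint targets.

    The pool is the regulators whose intermediate out-degree reaches the
    configured mean — a planted mechanism must drive enough evidence to be
    recoverable.  Mutually disjoint intermediate sets are preferred
    (rejection sampling, then best effort) so the mechanisms do not cancel
    one another at shared targets.
    """
    pool = [
        r for r in regulator_names(config)
        if r not in exclude
        and len(_intermediate_targets(graph, r)) >= config.out_degree_mean
    ]
    if len(pool) < config.n_planted:
        pool = [r for r in regulator_names(config) if r not in exclude]
    if len(pool) < config.n_planted:
        raise SimulationError("not enough regulators to draw planted mechanisms")
    chosen = None
    for _ in range(50):
        candidate = [str(e) for e in
                     rng.choice(pool, size=config.n_planted, replace=False)]
        covered: set[str] = set()
        disjoint = True
        for reg in candidate:
            targets = _intermediate_targets(graph, reg)
            if covered & targets:
                disjoint = False
                break
            covered |= targets
        chosen = candidate
        if disjoint:
            break
    else:
        logger.info("planted mechanisms share intermediates (accepted anyway)")
    return [(e, 1 if rng.random() < 0.5 else -1) for e in chosen]


def simulate_condition(
    graph: CausalGraph,
    config: SimulationConfig,
    planted: list[tuple[str, int]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DEProfile, SyntheticTruth]:
    """Simulate one condition's ternary DE profile from planted mechanisms.

    A transcript with intended sign ``s`` is observed as ``s`` with
    probability (1-eps)(1-pi), as ``-s`` with probability eps(1-pi), and is
    dropped (0) with probability pi; background transcripts are called
    changed with probability beta, split by ``background_up_bias``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if planted is None:
        planted = _draw_planted(rng, config, graph)
    regs = set(regulator_names(config))
    for entity, sign in planted:
        if entity not in regs:
            raise SimulationError(
                f"planted entity {entity!r} is not in the regulator layer"
            )
        if sign not in (1, -1):
            raise SimulationError(f"planted sign must be +1/-1, got {sign!r}")
    universe = sorted(graph.transcript_nodes)
    intended, n_conflicts = intended_signs(graph, planted, config.depth_layers)

    calls: dict[str, int] = {}
    affected = [t for t in universe if intended.get(t, 0) != 0]
    signs = np.array([intended[t] for t in affected], dtype=int)
    dropped = rng.random(len(affected)) < config.dropout
    flipped = rng.random(len(affected)) < config.flip_noise
    observed = np.where(dropped, 0, np.where(flipped, -signs, signs))
    for t, o in zip(affected, observed):
        if o != 0:
            calls[t] = int(o)

    background = [t for t in universe if intended.get(t, 0) == 0]
    changed = rng.random(len(background)) < config.background_rate
    up = rng.random(len(background)) < config.background_up_bias
    n_background = 0
    for t, ch, u in zip(background, changed, up):
        if ch:
            calls[t] = 1 if u else -1
            n_background += 1

    truth = SyntheticTruth(
        planted=list(planted),
        intended=intended,
        n_conflicting_transcripts=n_conflicts,
        n_flipped=int(np.count_nonzero(flipped & ~dropped)),
        n_dropped=int(np.count_nonzero(dropped)),
        n_background=n_background,
        config=asdict(config),
    )
    return DEProfile(frozenset(universe), calls), truth


def simulate_paired(
    graph: CausalGraph, config: SimulationConfig
) -> tuple[tuple[DEProfile, SyntheticTruth], tuple[DEProfile, SyntheticTruth]]:
    """Two conditions whose planted mechanisms overlap by ``overlap_fraction``.

    System A receives ``n_planted`` mechanisms; system B keeps
    ``round(f * n_planted)`` of them (same signs) and draws the remainder
    fresh from the unused regulators.  Noise is independent per system.
    """
    if config.n_planted < 1:
        raise SimulationError("simulate_paired needs n_planted >= 1")
    rng = np.random.default_rng(config.seed)
    planted_a = _draw_planted(rng, config, graph)
    n_shared = int(np.floor(config.overlap_fraction * config.n_planted + 0.5))
    shared = planted_a[:n_shared]
    n_fresh = config.n_planted - n_shared
    exclude = {e for e, _ in planted_a}
    if n_fresh:
        fresh_config = dataclasses.replace(config, n_planted=n_fresh)
        fresh = _draw_planted(rng, fresh_config, graph, exclude=exclude)
    else:
        fresh = []
    planted_b = shared + fresh

    rng_a = np.random.default_rng(rng.integers(2**31))
    rng_b = np.random.default_rng(rng.integers(2**31))
    return (
        simulate_condition(graph, config, planted=planted_a, rng=rng_a),
        simulate_condition(graph, config, planted=planted_b, rng=rng_b),
    )


def write_regulator_annotations(config: SimulationConfig, path) -> None:
    """GMT table assigning each regulator its own synthetic process."""
    with open(path, "w", encoding="utf-8") as fh:
        for reg in regulator_names(config):
            fh.write(f"PROC_{reg}\tsynthetic process driven by {reg}\t{reg}\n")


# -- recovery scoring --------------------------------------------------------

def recovery_metrics(
    results: list[HypothesisResult], truth: SyntheticTruth, k: int
) -> dict:
    """How well the ranked hypotheses recover the planted mechanisms.

    ``recall_at_k`` is the fraction of planted (entity, sign) pairs appearing
    in the top ``k`` with the correct sign; ``sign_accuracy`` is computed over
    the planted entities recovered in the top ``k`` in either direction.
    """
    if not truth.planted:
        logger.warning("empty truth: recovery metrics undefined")
        return {"recall_at_k": None, "sign_accuracy": None,
                "median_rank_of_planted": None, "k": k}
    ranked = [r for r in results if r.rank is not None]
    if not ranked:
        raise SimulationError("results must be ranked before recovery scoring")
    top = {r.label for r in ranked if r.rank <= k}
    rank_by_label = {r.label: r.rank for r in ranked}
    worst = len(ranked) + 1

    hits = 0
    recovered = 0
    correct_sign = 0
    planted_ranks = []
    for entity, sign in truth.planted:
        want = f"{entity}{'+' if sign == 1 else '-'}"
        other = f"{entity}{'-' if sign == 1 else '+'}"
        if want in top:
            hits += 1
        if want in top or other in top:
            recovered += 1
            if want in top:
                correct_sign += 1
        planted_ranks.append(rank_by_label.get(want, worst))
    return {
        "recall_at_k": hits / len(truth.planted),
        "sign_accuracy": (correct_sign / recovered) if recovered else None,
        "median_rank_of_planted": float(np.median(planted_ranks)),
        "k": k,
    }
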