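"""End-to-end simulation benchmarks: planted-mechanism recovery and paired-
condition translatability.

These routines run the full pipeline — generate a knowledgebase, simulate
profiles, score and rank hypotheses, summarise processes — over many seeds and
report aggregate metrics.  They are what the package's own validation (and any
study of parameter sensitivity) is built on.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .networks import (
    average_linkage_clusters,
    eliminate_redundant_hypotheses,
    explanation_vectors,
    map_processes,
)
from .scoring import rank_and_filter, score_all_hypotheses
from .simulate import (
    SimulationConfig,
    generate_knowledgebase,
    recovery_metrics,
    regulator_names,
    simulate_condition,
    simulate_paired,
)
from .translatability import ConditionResult, build_matrix, direction_concordance

logger = logging.getLogger(__name__)


def _child_seeds(base_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(int(base_seed) % (2**31)).generate_state(n) % (2**31)


def recovery_benchmark(
    config: SimulationConfig, n_seeds: int, k: int, base_seed: int = 0
) -> dict:
    """Mean recall@k (and friends) of planted mechanisms over ``n_seeds`` runs.

    Each run regenerates the knowledgebase and condition under a fresh seed
    derived from ``base_seed``, scores every hypothesis, ranks, and measures
    how many planted (regulator, direction) mechanisms appear in the top k.
    """
    recalls, sign_accs, median_ranks = [], [], []
    for seed in _child_seeds(base_seed, n_seeds):
        run_config = dataclasses.replace(config, seed=int(seed))
        graph = generate_knowledgebase(run_config)
        profile, truth = simulate_condition(graph, run_config)
        ranked = rank_and_filter(
            score_all_hypotheses(graph, profile, depth=run_config.depth_layers,
                                 seed=int(seed))
        )
        metrics = recovery_metrics(ranked, truth, k)
        recalls.append(metrics["recall_at_k"])
        if metrics["sign_accuracy"] is not None:
            sign_accs.append(metrics["sign_accuracy"])
        median_ranks.append(metrics["median_rank_of_planted"])
    return {
        "mean_recall_at_k": float(np.mean(recalls)),
        "min_recall_at_k": float(np.min(recalls)),
        "per_seed_recall": recalls,
        "mean_sign_accuracy": float(np.mean(sign_accs)) if sign_accs else None,
        "median_rank_of_planted": float(np.median(median_ranks)),
        "k": k,
        "n_seeds": n_seeds,
    }


def _condition_result(cid, graph, profile, config, seed) -> ConditionResult:
    """Full network construction for one condition: score, rank, cluster,
    eliminate redundant and surrogate hypotheses, then summarise the
    surviving hypotheses at the process level."""
    ranked = rank_and_filter(
        score_all_hypotheses(graph, profile, depth=config.depth_layers,
                             seed=int(seed))
    )
    annotations = {f"PROC_{reg}": {reg} for reg in regulator_names(config)}
    vectors = explanation_vectors(ranked, graph, profile,
                                  depth=config.depth_layers)
    if vectors:
        kept, _ = eliminate_redundant_hypotheses(ranked, vectors)
        kept_labels = {r.label for r in kept}
        kept_vectors = [v for v in vectors if v.label in kept_labels]
        clusters = (
            average_linkage_clusters(kept_vectors, ranked)
            if kept_vectors else None
        )
    else:
        kept, clusters = [], None
    calls = map_processes(kept, annotations, clusters) if kept else []
    return ConditionResult(cid, ranked, calls, clusters)


def paired_shared_fraction(
    config: SimulationConfig,
    overlap_fractions=(0.0, 0.5, 1.0),
    n_seeds: int = 50,
    base_seed: int = 0,
) -> dict[float, float]:
    """Mean process-level shared fraction between paired conditions, per
    planted-mechanism overlap fraction.

    For each seed, two conditions sharing ``round(f * n_planted)`` mechanisms
    are simulated on a common knowledgebase, both are run through scoring and
    process summarisation, and the fraction of system-A processes also called
    in system B is averaged over seeds.
    """
    out: dict[float, float] = {}
    for f in overlap_fractions:
        shared_values = []
        for seed in _child_seeds(base_seed + int(round(1000 * f)) + 1, n_seeds):
            run_config = dataclasses.replace(
                config, overlap_fraction=float(f), seed=int(seed)
            )
            graph = generate_knowledgebase(run_config)
            (prof_a, _), (prof_b, _) = simulate_paired(graph, run_config)
            cond_a = _condition_result("A", graph, prof_a, run_config, seed)
            cond_b = _condition_result("B", graph, prof_b, run_config, seed + 1)
            matrix = build_matrix([cond_a, cond_b])
            shared, _, _ = direction_concordance(matrix, "A", "B")
            if shared is not None:
                shared_values.append(shared)
        out[float(f)] = float(np.mean(shared_values)) if shared_values else np.nan
        logger.info("overlap f=%.2f: mean shared fraction %.3f over %d seeds",
                    f, out[float(f)], len(shared_values))
    return out
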