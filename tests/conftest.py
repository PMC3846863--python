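import itertools

import numpy as np
import pandas as pd
import pytest

from crengine import CausalGraph, CausalStatement, DEProfile


@pytest.fixture
def chain_graph():
    """u -(+)-> a -(-)-> t1, plus u -(+)-> t2."""
    return CausalGraph(
        [
            CausalStatement("u", 1, "a", "activity"),
            CausalStatement("a", -1, "t1", "transcript"),
            CausalStatement("u", 1, "t2", "transcript"),
        ]
    )


def random_graph(rng, n_nodes=8, n_transcripts=3, n_edges=12, p_negative=0.4):
    """Small random signed graph; the last ``n_transcripts`` nodes are leaves."""
    nodes = [f"n{i}" for i in range(n_nodes - n_transcripts)]
    txs = [f"t{i}" for i in range(n_transcripts)]
    statements = []
    for _ in range(n_edges):
        source = nodes[rng.integers(len(nodes))]
        if rng.random() < 0.5:
            target = txs[rng.integers(len(txs))]
            layer = "transcript"
        else:
            target = nodes[rng.integers(len(nodes))]
            layer = "activity"
        sign = -1 if rng.random() < p_negative else 1
        statements.append(CausalStatement(source, sign, target, layer))
    # guarantee at least one transcript edge so the graph is usable
    statements.append(CausalStatement(nodes[0], 1, txs[0], "transcript"))
    return CausalGraph(statements)


def random_profile(rng, universe, change_rate=0.5):
    calls = {}
    for g in universe:
        r = rng.random()
        if r < change_rate / 2:
            calls[g] = 1
        elif r < change_rate:
            calls[g] = -1
    return DEProfile(frozenset(universe), calls)


def walk_sign_oracle(graph, entity, sign, depth):
    """Brute-force enumeration of every directed walk of length <= depth.

    Transcript nodes are terminal.  Returns {transcript: set of net signs}.
    """
    reached = {}

    def rec(node, acc, d):
        if d >= 1 and graph.is_transcript(node):
            reached.setdefault(node, set()).add(acc)
            return
        if d == depth:
            return
        for target, edge_sign in graph.out_edges(node):
            rec(target, acc * edge_sign, d + 1)

    rec(entity, sign, 0)
    return reached


def correctness_tail_by_enumeration(q_plus, q_minus, m_plus, m_minus, N, s_obs):
    """Exhaustive label-permutation oracle for the correctness p-value.

    Enumerates every placement of the m_plus up and m_minus down calls over N
    genes (the first q_plus genes are predicted up, the next q_minus down).
    """
    genes = range(N)
    hits = total = 0
    for ups in itertools.combinations(genes, m_plus):
        rest = [g for g in genes if g not in ups]
        for downs in itertools.combinations(rest, m_minus):
            a = sum(1 for g in ups if g < q_plus)
            c = sum(1 for g in ups if q_plus <= g < q_plus + q_minus)
            b = sum(1 for g in downs if g < q_plus)
            d = sum(1 for g in downs if q_plus <= g < q_plus + q_minus)
            total += 1
            hits += (a - b - c + d) >= s_obs
    return hits / total


@pytest.fixture
def table2_affymetrix():
    """KLF4 fold changes measured on arrays for eight cardiotoxic compounds."""
    compounds = [
        "Amiodarone", "Amitryptiline", "Cyclosporine", "Dexamethasone",
        "Dobutamine", "Doxorubicin", "Loratadine", "Mitoxantrone",
    ]
    fold_changes = [1.62, 2.3, 1.84, 2.14, 1.93, -4.92, 2.1, 2.06]
    return pd.DataFrame(
        {
            "gene_id": compounds,
            "fold_change": fold_changes,
            "p_value": [0.001] * len(compounds),
        }
    )
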