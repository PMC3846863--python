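"""Hypothesis scoring: outcome counts, enrichment and correctness p-values, ranking.

Every non-transcript entity of the knowledgebase, in both assumed directions of
activity change, is a candidate upstream hypothesis.  Against a ternary DE
profile a hypothesis accrues

* ``n_correct``   — measured, changed transcripts whose observed direction
  matches the propagated prediction,
* ``n_incorrect`` — changed transcripts observed in the opposite direction,
* ``score = n_correct - n_incorrect`` — the ranking statistic.

Two significance measures accompany the score.  The *enrichment* p-value is
the upper-tail hypergeometric probability of finding ``n_correct +
n_incorrect`` changed genes among the hypothesis's unambiguous downstream
predictions.  The *correctness* p-value is the probability, under uniform
re-assignment of the observed up/down calls across the measured universe
(margins fixed), of a score at least as large as the observed one; it is
computed exactly by convolving the multivariate-hypergeometric occupancy of
the predicted-up and predicted-down slots, or by a chained-hypergeometric
Monte Carlo when the exact convolution is too large.

Ranking sorts by score (descending), breaking ties by smaller enrichment p,
then smaller correctness p, then hypothesis label; the significance filter
keeps hypotheses with at least ``min_support`` correct genes, both p-values
below the cutoff, and rank within ``max_rank`` (defaults 3, 0.01, 35).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom

from .de_profiles import DEProfile
from .knowledgebase import AMBIGUOUS, CausalGraph, PredictionSet, downstream_predictions

logger = logging.getLogger(__name__)

_TINY = 5e-324  # smallest positive double; p-values are never reported as 0

DEFAULT_MIN_SUPPORT = 3
DEFAULT_P_CUT = 0.01
DEFAULT_MAX_RANK = 35


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class Hypothesis:
    """A candidate upstream cause: an entity plus an assumed direction."""

    entity: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ScoringError(f"hypothesis sign must be +1 or -1, got {self.sign!r}")

    @property
    def label(self) -> str:
        return f"{self.entity}{'+' if self.sign == 1 else '-'}"


@dataclass
class HypothesisResult:
    hypothesis: Hypothesis
    q_plus: int
    q_minus: int
    q_ambig: int
    n_correct: int
    n_incorrect: int
    n_ambig_changed: int
    score: int
    enrichment_p: float
    correctness_p: float
    rank: int | None = None
    significant: bool = False

    @property
    def label(self) -> str:
        return self.hypothesis.label


def count_outcomes(pred: PredictionSet, profile: DEProfile):
    """Compare predictions with observed calls, restricted to the measured universe.

    Returns ``(q_plus, q_minus, q_ambig, n_correct, n_incorrect,
    n_ambig_changed)``.  Ambiguous predictions never count as correct or
    incorrect; predictions for unmeasured genes are dropped (and logged).
    """
    dropped = [t for t in pred.predictions if t not in profile.universe]
    if dropped:
        logger.debug(
            "count_outcomes(%s): %d predicted transcripts not measured",
            pred.hypothesis_entity, len(dropped),
        )
    q_plus = q_minus = q_ambig = 0
    n_correct = n_incorrect = n_ambig_changed = 0
    for t, p in pred.predictions.items():
        if t not in profile.universe:
            continue
        obs = profile.call(t)
        if p is AMBIGUOUS:
            q_ambig += 1
            if obs != 0:
                n_ambig_changed += 1
            continue
        if p == 1:
            q_plus += 1
        else:
            q_minus += 1
        if obs == 0:
            continue
        if obs == p:
            n_correct += 1
        else:
            n_incorrect += 1
    return q_plus, q_minus, q_ambig, n_correct, n_incorrect, n_ambig_changed


# -- enrichment --------------------------------------------------------------

def enrichment_pvalue(N: int, m: int, K: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``N`` measured genes of which ``m`` are changed; ``K`` genes drawn (the
    hypothesis's unambiguous predictions); ``k`` of them changed.
    """
    for name, v in (("N", N), ("m", m), ("K", K), ("k", k)):
        if v < 0:
            raise ScoringError(f"{name} must be nonnegative, got {v}")
    if m > N or K > N or k > min(K, m):
        raise ScoringError(
            f"inconsistent counts N={N}, m={m}, K={K}, k={k}"
        )
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, m, K))
    if p <= 0.0 or not np.isfinite(p):
        support = np.arange(k, min(K, m) + 1)
        p = float(np.exp(logsumexp(hypergeom.logpmf(support, N, m, K))))
    return min(1.0, max(p, _TINY))


# -- correctness -------------------------------------------------------------

def _check_correctness_args(q_plus, q_minus, m_plus, m_minus, N, s_obs):
    for name, v in (("q_plus", q_plus), ("q_minus", q_minus),
                    ("m_plus", m_plus), ("m_minus", m_minus), ("N", N)):
        if v < 0:
            raise ScoringError(f"{name} must be nonnegative, got {v}")
    if q_plus + q_minus > N:
        raise ScoringError("q_plus + q_minus exceeds the universe size")
    if m_plus + m_minus > N:
        raise ScoringError("m_plus + m_minus exceeds the universe size")
    if s_obs > q_plus + q_minus:
        raise ScoringError(
            f"impossible score {s_obs} > q_plus + q_minus = {q_plus + q_minus}"
        )


def _canonical(q_plus, q_minus, m_plus, m_minus):
    """Swap the up/down roles to a canonical order.

    The null score distribution is invariant under exchanging
    (q_plus, m_plus) with (q_minus, m_minus): relabelling up calls as down and
    up slots as down slots maps the score onto itself.  Computing on the
    canonical form makes the exact value — and the Monte Carlo stream — agree
    bit-for-bit for mirror-image hypotheses.
    """
    a, b = (q_plus, m_plus), (q_minus, m_minus)
    if a < b:
        return q_minus, q_plus, m_minus, m_plus
    return q_plus, q_minus, m_plus, m_minus


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    invalid = (k < 0) | (k > n) | (n < 0)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(invalid, -np.inf, out)


def correctness_pvalue_exact(q_plus, q_minus, m_plus, m_minus, N, s_obs) -> float:
    """Exact tail probability P(S >= s_obs) of the score under the label-
    permutation null.

    The null reassigns the observed ``m_plus`` up and ``m_minus`` down calls
    uniformly at random over the ``N`` measured genes.  With ``a``/``b`` up/
    down calls landing on the ``q_plus`` predicted-up slots and ``c``/``d`` on
    the ``q_minus`` predicted-down slots, S = a - b - c + d.  The joint law of
    (a, b) is multivariate hypergeometric; (c, d) follows the same law on the
    reduced population, and the two are convolved exactly in log space.
    """
    _check_correctness_args(q_plus, q_minus, m_plus, m_minus, N, s_obs)
    q_plus, q_minus, m_plus, m_minus = _canonical(q_plus, q_minus, m_plus, m_minus)
    if s_obs <= -(q_plus + q_minus):
        return 1.0

    m_zero = N - m_plus - m_minus
    N2 = N - q_plus
    a, b, c, d = np.ix_(
        np.arange(min(q_plus, m_plus) + 1),
        np.arange(min(q_plus, m_minus) + 1),
        np.arange(min(q_minus, m_plus) + 1),
        np.arange(min(q_minus, m_minus) + 1),
    )
    zeros_in_a = q_plus - a - b
    log_pa = (
        _log_comb(m_plus, a)
        + _log_comb(m_minus, b)
        + _log_comb(m_zero, zeros_in_a)
        - _log_comb(N, q_plus)
    )
    # conditional multivariate hypergeometric for the q_minus slots
    log_pcd = (
        _log_comb(m_plus - a, c)
        + _log_comb(m_minus - b, d)
        + _log_comb(m_zero - zeros_in_a, q_minus - c - d)
        - _log_comb(N2, q_minus)
    )
    log_joint = log_pa + log_pcd
    mask = (a - b - c + d >= s_obs) & np.isfinite(log_joint)
    if not np.any(mask):
        return _TINY
    p = float(np.exp(logsumexp(log_joint[mask])))
    return min(1.0, max(p, _TINY))


def correctness_exact_cost(q_plus, q_minus, m_plus, m_minus) -> int:
    """Number of (a, b, c, d) enumeration terms of the exact convolution."""
    q_plus, q_minus, m_plus, m_minus = _canonical(q_plus, q_minus, m_plus, m_minus)
    return (
        (min(q_plus, m_plus) + 1)
        * (min(q_plus, m_minus) + 1)
        * (min(q_minus, m_plus) + 1)
        * (min(q_minus, m_minus) + 1)
    )


def correctness_pvalue_mc(
    q_plus, q_minus, m_plus, m_minus, N, s_obs, n_perm: int = 9999, seed=None
):
    """Monte Carlo estimate of the correctness p-value with add-one correction.

    Each permutation draws the slot occupancies through a chain of conditional
    hypergeometric draws (ups into up/down slots, then downs into the
    remaining slots), which is equivalent to a full label permutation but
    vectorises over permutations.  Returns ``(p_estimate, mc_stderr)``.
    """
    _check_correctness_args(q_plus, q_minus, m_plus, m_minus, N, s_obs)
    if n_perm < 100:
        raise ScoringError(f"n_perm must be >= 100, got {n_perm}")
    q_plus, q_minus, m_plus, m_minus = _canonical(q_plus, q_minus, m_plus, m_minus)
    if s_obs <= -(q_plus + q_minus):
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    rest = N - q_plus - q_minus
    # up calls into predicted-up slots, then predicted-down slots
    a = rng.hypergeometric(q_plus, N - q_plus, m_plus, size=n_perm) if m_plus else np.zeros(n_perm, int)
    c = (
        rng.hypergeometric(q_minus, rest, m_plus - a)
        if (m_plus and q_minus + rest) else np.zeros(n_perm, int)
    )
    # down calls into the slots left free of up calls
    free = N - m_plus
    if m_minus:
        b = rng.hypergeometric(q_plus - a, free - (q_plus - a), m_minus)
        free2 = free - (q_plus - a)
        d = rng.hypergeometric(q_minus - c, free2 - (q_minus - c), m_minus - b)
    else:
        b = d = np.zeros(n_perm, int)
    s = a - b - c + d
    hits = int(np.count_nonzero(s >= s_obs))
    p = (hits + 1) / (n_perm + 1)
    stderr = float(np.sqrt(p * (1 - p) / n_perm))
    return float(p), stderr


# -- full scoring ------------------------------------------------------------

def _hypothesis_seed(base_seed, entity, q_plus, q_minus, m_plus, m_minus, N):
    """Deterministic per-hypothesis MC seed, invariant under the up/down swap."""
    qp, qm, mp, mm = _canonical(q_plus, q_minus, m_plus, m_minus)
    key = f"{entity}|{qp}|{qm}|{mp}|{mm}|{N}".encode()
    return np.random.SeedSequence([int(base_seed) % (2**31), zlib.crc32(key)])


def score_all_hypotheses(
    graph: CausalGraph,
    profile: DEProfile,
    depth: int = 2,
    correctness_method: str = "auto",
    exact_max_terms: int = 200_000,
    n_perm: int = 1999,
    seed: int = 0,
    traverse_transcripts: bool = False,
) -> list[HypothesisResult]:
    """Score both directions of every non-transcript entity against ``profile``.

    Entities with no measured downstream prediction are skipped.  The
    correctness p-value uses the exact convolution when its enumeration stays
    within ``exact_max_terms`` (or always, with ``correctness_method='exact'``),
    and the Monte Carlo estimator otherwise; MC streams are seeded per
    hypothesis so results are reproducible and mirror-symmetric.
    """
    if correctness_method not in ("auto", "exact", "mc"):
        raise ScoringError(f"unknown correctness_method {correctness_method!r}")
    if not (graph.transcript_nodes & profile.universe):
        raise ScoringError(
            "no overlap between knowledgebase transcript nodes and the "
            "profile universe"
        )
    N = profile.n
    m_plus, m_minus = profile.m_plus, profile.m_minus
    m = m_plus + m_minus
    results: list[HypothesisResult] = []
    for entity in graph.non_transcript_entities():
        pred_plus = downstream_predictions(
            graph, entity, 1, depth, traverse_transcripts
        )
        if not any(t in profile.universe for t in pred_plus.predictions):
            continue
        for pred in (pred_plus, pred_plus.negated()):
            hyp = Hypothesis(entity, pred.hypothesis_sign)
            q_plus, q_minus, q_ambig, n_corr, n_inc, n_amb = count_outcomes(
                pred, profile
            )
            K = q_plus + q_minus
            k = n_corr + n_inc
            score = n_corr - n_inc
            enr = enrichment_pvalue(N, m, K, k) if K else 1.0
            if K == 0:
                cor = 1.0
            else:
                use_exact = correctness_method == "exact" or (
                    correctness_method == "auto"
                    and correctness_exact_cost(q_plus, q_minus, m_plus, m_minus)
                    <= exact_max_terms
                )
                if use_exact:
                    cor = correctness_pvalue_exact(
                        q_plus, q_minus, m_plus, m_minus, N, score
                    )
                else:
                    cor, _ = correctness_pvalue_mc(
                        q_plus, q_minus, m_plus, m_minus, N, score,
                        n_perm=n_perm,
                        seed=_hypothesis_seed(
                            seed, entity, q_plus, q_minus, m_plus, m_minus, N
                        ),
                    )
            results.append(
                HypothesisResult(
                    hyp, q_plus, q_minus, q_ambig, n_corr, n_inc, n_amb,
                    score, enr, cor,
                )
            )
    logger.info("scored %d hypotheses against %d measured genes", len(results), N)
    return results


def rank_and_filter(
    results: list[HypothesisResult],
    min_support: int = DEFAULT_MIN_SUPPORT,
    p_cut: float = DEFAULT_P_CUT,
    max_rank: int = DEFAULT_MAX_RANK,
) -> list[HypothesisResult]:
    """Rank hypotheses and flag the significant ones.

    Rank is the 1-based position after sorting by score descending, ties by
    smaller enrichment p, then smaller correctness p, then label.  A
    hypothesis is significant when it has at least ``min_support`` correctly
    explained genes, both p-values below ``p_cut`` and rank at most
    ``max_rank``.
    """
    ranked = sorted(
        results,
        key=lambda r: (-r.score, r.enrichment_p, r.correctness_p, r.label),
    )
    for i, r in enumerate(ranked, start=1):
        r.rank = i
        r.significant = (
            r.n_correct >= min_support
            and r.enrichment_p < p_cut
            and r.correctness_p < p_cut
            and r.rank <= max_rank
        )
    return ranked


def results_to_frame(results: list[HypothesisResult]):
    """Tabulate results in the standard output column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "hypothesis_id": r.hypothesis.entity,
                "sign": r.hypothesis.sign,
                "q_plus": r.q_plus,
                "q_minus": r.q_minus,
                "q_ambig": r.q_ambig,
                "n_correct": r.n_correct,
                "n_incorrect": r.n_incorrect,
                "score": r.score,
                "enrichment_p": r.enrichment_p,
                "correctness_p": r.correctness_p,
                "rank": r.rank,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def frame_to_results(frame) -> list[HypothesisResult]:
    """Rebuild :class:`HypothesisResult` objects from a results table."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            HypothesisResult(
                Hypothesis(str(row.hypothesis_id), int(row.sign)),
                int(row.q_plus), int(row.q_minus), int(row.q_ambig),
                int(row.n_correct), int(row.n_incorrect),
                0,
                int(row.score), float(row.enrichment_p), float(row.correctness_p),
                int(row.rank) if row.rank == row.rank else None,
                bool(row.significant),
            )
        )
    return out
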