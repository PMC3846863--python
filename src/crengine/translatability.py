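"""Cross-condition comparison of process-level causal calls.

Each experimental condition (compound × biological system, e.g. rat heart in
vivo vs H9C2 or primary cardiomyocyte cultures) yields ranked hypotheses and
process-level direction calls.  Stacking the calls of several conditions gives
a process × condition matrix of UP / DOWN / MIXED / ABSENT cells — the
heatmap view of translatability — from which per-compound concordance is
summarised: a process found in vivo *translates* to an in vitro system when it
is called there at all, and direction agreement is reported separately (MIXED
agrees only with MIXED).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .networks import HypothesisCluster, ProcessCall
from .scoring import HypothesisResult

logger = logging.getLogger(__name__)

ABSENT = "ABSENT"


class TranslatabilityError(ValueError):
    pass


@dataclass
class ConditionResult:
    """Scored, summarised output of one condition."""

    condition_id: str
    results: list[HypothesisResult]
    process_calls: list[ProcessCall]
    clusters: list[HypothesisCluster] | None = None


@dataclass
class TranslationMatrix:
    """Process × condition direction matrix with cells in
    {UP, DOWN, MIXED, ABSENT}."""

    cells: pd.DataFrame

    @property
    def processes(self) -> list[str]:
        return list(self.cells.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.cells.columns)

    def column(self, condition_id: str) -> pd.Series:
        if condition_id not in self.cells.columns:
            raise TranslatabilityError(f"unknown condition {condition_id!r}")
        return self.cells[condition_id]

    def to_tsv(self, path) -> None:
        self.cells.to_csv(path, sep="\t", index_label="process")

    @classmethod
    def from_tsv(cls, path) -> "TranslationMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="process"))


def build_matrix(
    conditions: list[ConditionResult], top_networks_only: bool = False
) -> TranslationMatrix:
    """Assemble the process × condition direction matrix.

    A cell carries the condition's process call when present — optionally only
    when the call is backed by a top-ranking network (a cluster of >= 3
    hypotheses with one ranked in the top 25) — and ABSENT otherwise.
    """
    if len(conditions) < 2:
        raise TranslatabilityError("need at least two conditions to compare")
    ids = [c.condition_id for c in conditions]
    if len(set(ids)) != len(ids):
        raise TranslatabilityError(f"duplicate condition ids in {ids}")
    rows: set[str] = set()
    per_condition: dict[str, dict[str, str]] = {}
    for cond in conditions:
        calls = {}
        for call in cond.process_calls:
            if top_networks_only and not call.backed_by_top_network:
                continue
            calls[call.process] = call.direction
        per_condition[cond.condition_id] = calls
        rows |= set(calls)
    frame = pd.DataFrame(
        {
            cid: [per_condition[cid].get(p, ABSENT) for p in sorted(rows)]
            for cid in ids
        },
        index=sorted(rows),
    )
    return TranslationMatrix(frame)


def direction_concordance(
    matrix: TranslationMatrix, reference_column: str, target_column: str
):
    """Concordance of ``target_column`` with the processes of the reference.

    Over processes non-ABSENT in the reference: the fraction also non-ABSENT
    in the target, and — among those shared — the fractions with the same and
    with the opposite direction (MIXED matches only MIXED and is neither same
    nor opposite relative to UP/DOWN... it counts as "other").  Returns
    ``(shared_fraction, same_direction_fraction, opposite_fraction)``; all
    None when the reference column is entirely ABSENT.
    """
    ref = matrix.column(reference_column)
    tgt = matrix.column(target_column)
    present = ref[ref != ABSENT]
    if present.empty:
        logger.warning(
            "reference column %r has no process calls; concordance undefined",
            reference_column,
        )
        return None, None, None
    shared = [p for p in present.index if tgt[p] != ABSENT]
    shared_fraction = len(shared) / len(present)
    if not shared:
        return shared_fraction, None, None
    same = sum(1 for p in shared if ref[p] == tgt[p])
    opposite = sum(
        1
        for p in shared
        if {ref[p], tgt[p]} == {"UP", "DOWN"}
    )
    return shared_fraction, same / len(shared), opposite / len(shared)


def summarize_compound(
    matrix: TranslationMatrix,
    compound: str,
    in_vivo_col: str,
    in_vitro_cols: list[str],
) -> dict:
    """Per-compound translatability report.

    Counts the in vivo processes and, per in vitro system, how many of them
    are found there at all, with the same direction, and with the opposite
    direction; flags whether at least one process translated anywhere.
    """
    ref = matrix.column(in_vivo_col)
    in_vivo_processes = [p for p in ref.index if ref[p] != ABSENT]
    report = {
        "compound": compound,
        "in_vivo_condition": in_vivo_col,
        "n_in_vivo_processes": len(in_vivo_processes),
        "systems": {},
        "translated_any": False,
    }
    for col in in_vitro_cols:
        tgt = matrix.column(col)
        shared = [p for p in in_vivo_processes if tgt[p] != ABSENT]
        same = [p for p in shared if ref[p] == tgt[p]]
        opposite = [p for p in shared if {ref[p], tgt[p]} == {"UP", "DOWN"}]
        report["systems"][col] = {
            "n_translated_any_direction": len(shared),
            "n_translated_same_direction": len(same),
            "n_translated_opposite_direction": len(opposite),
            "processes_translated": sorted(shared),
        }
        if shared:
            report["translated_any"] = True
    return report
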