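"""Differential-expression tables and their discretization into ternary profiles.

A DE table holds one row per gene with a *signed linear* fold change (|fc| >= 1,
negative = down-regulated, e.g. -4.92 means 4.92-fold down) and a raw p-value,
optionally with a BH-adjusted p.  Discretization against a fold-change cutoff
(default 1.3) and a significance cutoff yields a ternary profile: per gene an
observed call in {+1, -1, 0} over the measured-gene universe.  The universe is
always the full set of measured genes, not just the called ones — both the
enrichment and the correctness null condition on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene_id", "fold_change", "p_value")


class DEProfileError(ValueError):
    pass


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DEProfileError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_to_signed_linear(log2_fc) -> np.ndarray:
    """Convert log2 fold changes to the signed linear convention (±2^|lfc|)."""
    lfc = np.asarray(log2_fc, dtype=float)
    return np.where(lfc >= 0, 2.0 ** lfc, -(2.0 ** (-lfc)))


def signed_linear_to_log2(fc) -> np.ndarray:
    """Inverse of :func:`log2_to_signed_linear`."""
    fc = np.asarray(fc, dtype=float)
    if np.any(np.abs(fc) < 1):
        raise DEProfileError("signed linear fold changes must have |fc| >= 1")
    return np.sign(fc) * np.log2(np.abs(fc))


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DEProfileError(f"DE table missing columns: {missing}")
    if np.any(np.abs(table["fold_change"].to_numpy(float)) < 1):
        raise DEProfileError("fold changes must be signed linear with |fc| >= 1")
    p = table["p_value"].to_numpy(float)
    if np.any((p < 0) | (p > 1)):
        raise DEProfileError("p_value outside [0, 1]")
    return table


def read_de_table(path) -> pd.DataFrame:
    """Read a DE table TSV (``gene_id  fold_change  p_value  [adj_p]``)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    return validate_de_table(table)


def write_de_table(table: pd.DataFrame, path) -> None:
    validate_de_table(table).to_csv(path, sep="\t", index=False)


def collapse_probes(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated gene_ids (e.g. multiple probesets per gene) to one row.

    The row with the largest |fold_change| wins; ties go to the smaller
    p-value, then to the first occurrence.
    """
    validate_de_table(table)
    if table["gene_id"].is_unique:
        return table.reset_index(drop=True)
    work = table.assign(
        _absfc=table["fold_change"].abs(), _order=np.arange(len(table))
    )
    work = work.sort_values(
        ["_absfc", "p_value", "_order"], ascending=[False, True, True], kind="stable"
    )
    work = work.drop_duplicates("gene_id", keep="first")
    return (
        work.sort_values("_order")
        .drop(columns=["_absfc", "_order"])
        .reset_index(drop=True)
    )


@dataclass
class DEProfile:
    """Ternary observed-change profile over a measured-gene universe.

    ``calls`` stores only the non-zero calls; genes in the universe absent from
    ``calls`` are unchanged (0).
    """

    universe: frozenset
    calls: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.calls = {g: int(c) for g, c in self.calls.items() if c != 0}
        stray = set(self.calls) - self.universe
        if stray:
            raise DEProfileError(
                f"{len(stray)} called genes outside the universe, e.g. "
                f"{sorted(stray)[:3]}"
            )
        if any(c not in (1, -1) for c in self.calls.values()):
            raise DEProfileError("calls must be +1, -1 or 0")

    def call(self, gene: str) -> int:
        return self.calls.get(gene, 0)

    @property
    def n(self) -> int:
        return len(self.universe)

    @property
    def m_plus(self) -> int:
        return sum(1 for c in self.calls.values() if c == 1)

    @property
    def m_minus(self) -> int:
        return sum(1 for c in self.calls.values() if c == -1)

    def negated(self) -> "DEProfile":
        return DEProfile(self.universe, {g: -c for g, c in self.calls.items()})


def discretize(
    table: pd.DataFrame,
    fc_cutoff: float = 1.3,
    p_cutoff: float = 0.05,
    use_adjusted: bool = True,
    universe=None,
) -> DEProfile:
    """Call each gene +1/-1/0 by fold-change magnitude and significance.

    A gene is called sign(fc) when |fc| >= ``fc_cutoff`` and its (adjusted, or
    raw when ``use_adjusted`` is off) p-value is below ``p_cutoff``.  When
    adjusted p-values are requested but absent from the table they are computed
    with :func:`bh_adjust`.  Genes of the universe missing from the table get 0.
    """
    if fc_cutoff < 1:
        raise DEProfileError(f"fc_cutoff must be >= 1 (linear scale), got {fc_cutoff}")
    table = collapse_probes(table)
    genes = table["gene_id"].astype(str)
    if universe is None:
        universe = frozenset(genes)
    else:
        universe = frozenset(universe)
        extra = set(genes) - universe
        if extra:
            raise DEProfileError(
                f"universe must contain every gene in the table; missing e.g. "
                f"{sorted(extra)[:3]}"
            )
    fc = table["fold_change"].to_numpy(float)
    if use_adjusted:
        if "adj_p" in table.columns and table["adj_p"].notna().all():
            p = table["adj_p"].to_numpy(float)
        else:
            p = bh_adjust(table["p_value"].to_numpy(float))
    else:
        p = table["p_value"].to_numpy(float)
    called = (np.abs(fc) >= fc_cutoff) & (p < p_cutoff)
    calls = {
        g: int(np.sign(f)) for g, f, c in zip(genes, fc, called) if c
    }
    logger.info(
        "discretize: %d/%d genes called (%d up, %d down) at |fc|>=%g, p<%g",
        len(calls), len(universe),
        sum(1 for v in calls.values() if v > 0),
        sum(1 for v in calls.values() if v < 0),
        fc_cutoff, p_cutoff,
    )
    return DEProfile(universe, calls)


def read_profile(path) -> DEProfile:
    """Read a profile TSV (``gene_id  call``) covering the whole universe."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    if list(frame.columns) != ["gene_id", "call"]:
        raise DEProfileError(f"{path}: expected columns gene_id, call")
    return DEProfile(
        frozenset(frame["gene_id"]),
        {g: int(c) for g, c in zip(frame["gene_id"], frame["call"]) if c != 0},
    )


def write_profile(profile: DEProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tcall\n")
        for g in sorted(profile.universe):
            fh.write(f"{g}\t{profile.call(g)}\n")
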