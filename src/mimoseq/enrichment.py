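"""Tetramer-fraction clonotype enrichment.

Antigen-specific clonal lineages are identified by comparing clonotype
frequencies between tetramer-positive and tetramer-negative sorted
fractions: a lineage counts as specific when it is clonally expanded
(>= ``min_cells`` cells in the positive fraction) and at least
``min_fold``-fold enriched in frequency in the positive fraction relative
to the negative fraction.  Because specific lineages are often absent from
the negative fraction, the fold denominator takes an additive pseudocount;
the unadjusted fold (infinite for absent lineages) is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

__all__ = [
    "ClonotypeCountTable",
    "EnrichedLineage",
    "fraction_frequencies",
    "select_enriched",
    "motif_share",
]


@dataclass
class ClonotypeCountTable:
    """Per-clonotype cell counts in the tetramer-positive/negative fractions."""

    rows: dict[str, tuple[int, int]]  # id -> (n_pos, n_neg)
    totals: Optional[tuple[int, int]] = None  # (N_pos, N_neg); defaults to sums

    def __post_init__(self) -> None:
        if any(p < 0 or n < 0 for p, n in self.rows.values()):
            raise ValueError("counts must be >= 0")
        sums = (
            sum(p for p, _ in self.rows.values()),
            sum(n for _, n in self.rows.values()),
        )
        if self.totals is None:
            self.totals = sums
        elif self.totals[0] < sums[0] or self.totals[1] < sums[1]:
            raise ValueError("totals cannot be smaller than the column sums")

    @property
    def n_pos_total(self) -> int:
        return self.totals[0]

    @property
    def n_neg_total(self) -> int:
        return self.totals[1]


def fraction_frequencies(
    table: ClonotypeCountTable,
) -> dict[str, tuple[float, float]]:
    """Per-clonotype (freq_pos, freq_neg); each fraction normalised by its total."""
    N_pos, N_neg = table.totals
    if N_pos <= 0 or N_neg <= 0:
        raise ValueError("fraction totals must be positive")
    return {
        cid: (p / N_pos, n / N_neg) for cid, (p, n) in table.rows.items()
    }


@dataclass
class EnrichedLineage:
    clonotype_id: str
    n_pos: int
    n_neg: int
    freq_pos: float
    freq_neg_adjusted: float
    fold: float  # freq_pos / freq_neg_adjusted
    fold_unadjusted: float = math.inf  # inf when absent from the negative fraction


def select_enriched(
    table: ClonotypeCountTable,
    min_cells: int = 3,
    min_fold: float = 5.0,
    pseudocount: float = 1.0,
) -> list[EnrichedLineage]:
    """Clonally expanded, tetramer-enriched lineages.

    A lineage passes iff ``n_pos >= min_cells`` and
    ``(n_pos/N_pos) / ((n_neg + pseudocount)/(N_neg + pseudocount)) >= min_fold``.
    Output is sorted by adjusted fold descending (ties by id).
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if min_fold <= 0:
        raise ValueError("min_fold must be > 0")
    N_pos, N_neg = table.totals
    if N_pos <= 0 or N_neg <= 0:
        raise ValueError("fraction totals must be positive")
    out = []
    for cid, (n_pos, n_neg) in table.rows.items():
        if n_pos < min_cells:
            continue
        freq_pos = n_pos / N_pos
        freq_neg_adj = (n_neg + pseudocount) / (N_neg + pseudocount)
        # pseudocount 0 and an absent lineage: infinitely enriched
        fold = freq_pos / freq_neg_adj if freq_neg_adj > 0 else math.inf
        if fold >= min_fold:
            raw = (
                (freq_pos / (n_neg / N_neg)) if n_neg > 0 else math.inf
            )
            out.append(
                EnrichedLineage(
                    clonotype_id=cid,
                    n_pos=n_pos,
                    n_neg=n_neg,
                    freq_pos=freq_pos,
                    freq_neg_adjusted=freq_neg_adj,
                    fold=fold,
                    fold_unadjusted=raw,
                )
            )
    return sorted(out, key=lambda e: (-e.fold, e.clonotype_id))


def motif_share(
    enriched: Sequence[EnrichedLineage] | Sequence[str],
    predicate: Callable[[object], bool],
) -> tuple[int, int, float]:
    """Fraction of enriched lineages satisfying a clonotype property.

    Returns ``(k, n, k/n)`` -- e.g. 23 of 61 lineages using TRAJ7 -> 0.377.
    """
    items = list(enriched)
    if not items:
        raise ValueError("no enriched lineages")
    k = sum(1 for x in items if predicate(x))
    return k, len(items), k / len(items)
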