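"""Public-TCR analytics over clonotype tables.

Recurring CDR3 motifs (e.g. the PPG beta-chain motif of p15E-reactive
clones), shared-CDR3 grouping across clones and mice, V/J gene-usage
tables, and a convergent-recombination index counting distinct nucleotide
encodings per amino-acid CDR3.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .germline import translate
from .repertoire import Clonotype

__all__ = [
    "MotifCount",
    "UsageTable",
    "count_motif",
    "group_shared_cdr3",
    "gene_usage",
    "convergence_index",
    "strip_allele",
    "collapse_family",
]

_SEGMENT_FIELDS = {
    "TRAV": "v_alpha",
    "TRAJ": "j_alpha",
    "TRBV": "v_beta",
    "TRBJ": "j_beta",
    "TRBD": "d_beta",
}


@dataclass
class MotifCount:
    motif: str
    n_matching: int
    n_total: int
    matching_ids: list


def count_motif(
    cdr3_list: Sequence[str] | Sequence[tuple[str, str]], motif: str
) -> MotifCount:
    """Count CDR3s containing ``motif`` as a contiguous substring.

    Matching is literal (no regex classes); each sequence counts once.
    Items may be bare sequences or ``(id, sequence)`` pairs.
    """
    if not motif or not motif.isupper() or not motif.isalpha():
        raise ValueError("motif must be a non-empty uppercase amino-acid string")
    matching = []
    total = 0
    for i, item in enumerate(cdr3_list):
        ident, seq = item if isinstance(item, tuple) else (i, item)
        total += 1
        if motif in seq:
            matching.append(ident)
    return MotifCount(motif=motif, n_matching=len(matching), n_total=total, matching_ids=matching)


def group_shared_cdr3(
    clonotypes: Sequence[Clonotype], chain: str = "alpha"
) -> list[list[Clonotype]]:
    """Partition clonotypes by exact CDR3 amino-acid identity on one chain.

    Groups are sorted by size descending (ties by CDR3 sequence), exposing
    public CDR3s shared across beta-chain-divergent clones.
    """
    if chain not in ("alpha", "beta"):
        raise ValueError("chain must be 'alpha' or 'beta'")
    attr = "cdr3_alpha_aa" if chain == "alpha" else "cdr3_beta_aa"
    groups: dict[str, list[Clonotype]] = defaultdict(list)
    for c in clonotypes:
        groups[getattr(c, attr)].append(c)
    return [
        members
        for _, members in sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]


def strip_allele(gene: str) -> str:
    """Drop an IMGT allele suffix: TRAV10*01 -> TRAV10."""
    return gene.split("*", 1)[0]


def collapse_family(gene: str) -> str:
    """Collapse a gene label to its family: TRAV10D -> TRAV10, TRAV7-2 -> TRAV7."""
    g = strip_allele(gene)
    g = re.sub(r"-\d+$", "", g)
    return g[:-1] if g.endswith("D") and len(g) > 1 else g


@dataclass
class UsageTable:
    segment_kind: str
    counts: dict[str, int]
    fractions: dict[str, float]


def gene_usage(
    clonotypes: Sequence[Clonotype],
    segment_kind: str,
    weight: str = "by_clone",
    collapse_families: bool = False,
) -> UsageTable:
    """Gene-segment usage across clonotypes.

    ``by_clone`` counts each lineage once; ``by_cell`` weights by clone
    size.  Labels are compared after stripping allele suffixes; distinct
    family members (TRAV10 vs TRAV10D) stay separate unless
    ``collapse_families``.
    """
    try:
        attr = _SEGMENT_FIELDS[segment_kind]
    except KeyError:
        raise ValueError(f"unknown segment kind {segment_kind!r}") from None
    if weight not in ("by_clone", "by_cell"):
        raise ValueError("weight must be 'by_clone' or 'by_cell'")
    counts: dict[str, int] = defaultdict(int)
    for c in clonotypes:
        gene = getattr(c, attr)
        if gene is None:
            continue
        label = collapse_family(gene) if collapse_families else strip_allele(gene)
        counts[label] += c.size if weight == "by_cell" else 1
    total = sum(counts.values())
    fractions = {g: n / total for g, n in counts.items()} if total else {}
    return UsageTable(segment_kind=segment_kind, counts=dict(counts), fractions=fractions)


def convergence_index(
    records: Iterable[tuple[str, str]] | Iterable[Mapping[str, str]],
) -> dict[str, int]:
    """Distinct nucleotide encodings observed per amino-acid CDR3.

    Public CDR3s formed by convergent recombination show several nucleotide
    sequences translating to the same junction.  Records are ``(cdr3_aa,
    cdr3_nt)`` pairs or mappings with those keys; a record whose nucleotide
    sequence does not translate to its amino-acid sequence is an error.
    """
    encodings: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        if isinstance(rec, Mapping):
            aa, nt = rec["cdr3_aa"], rec["cdr3_nt"]
        else:
            aa, nt = rec
        if translate(nt) != aa:
            raise ValueError(f"nucleotide CDR3 {nt} does not translate to {aa}")
        encodings[aa].add(nt)
    return {aa: len(s) for aa, s in encodings.items()}
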