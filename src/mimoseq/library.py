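"""NNK mimotope library design and selection-round deep-sequencing analysis.

The mimotope discovery strategy diversifies the TCR-contacting positions of
an MHC-I peptide (for p15E/H-2Kb: KSPWFTTL, positions 1, 4, 6 and 7 ->
template XSPXFXXL) with NNK degenerate codons, displays the variants as
single-chain pMHC on yeast, and enriches TCR-binding clones over successive
selection rounds.  This module designs such libraries and turns per-round
deep sequencing into peptide count tables, read-count-weighted positional
amino-acid preference matrices (the heat-map source) and ranked mimotope
candidates.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .germline import PREFERRED_CODON, translate

__all__ = [
    "AA_ORDER",
    "LibraryDesign",
    "PeptideCountTable",
    "PositionPreferenceMatrix",
    "MimotopeCandidate",
    "MergeResult",
    "RegionResult",
    "design_library",
    "codon_table",
    "diversity",
    "DiversityReport",
    "merge_pairs",
    "reverse_complement",
    "extract_region",
    "translate_filter",
    "tally_peptides",
    "preference_matrix",
    "pooled_counts",
    "enrichment_trajectory",
    "rank_mimotopes",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

_DEGENERATE_THIRD = {"NNK": "GT", "NNS": "GC", "NNN": "ACGT"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def codon_table(codon_scheme: str) -> dict[str, str]:
    """Enumerate the degenerate codon set with translations ('*' = stop)."""
    try:
        third = _DEGENERATE_THIRD[codon_scheme]
    except KeyError:
        raise ValueError(f"unknown codon scheme {codon_scheme!r}") from None
    return {
        c: translate(c)
        for c in ("".join(b) for b in itertools.product("ACGT", "ACGT", third))
    }


@dataclass(frozen=True)
class LibraryDesign:
    """A saturation-mutagenesis peptide library.

    ``diversified_positions`` are 1-based positions carrying the degenerate
    codon; all other positions are fixed at the template residue via
    ``fixed_codons``.
    """

    template_peptide: str
    diversified_positions: frozenset[int]
    codon_scheme: str = "NNK"
    fixed_codons: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.template_peptide)
        for p in self.diversified_positions:
            if not 1 <= p <= L:
                raise ValueError(f"diversified position {p} outside 1..{L}")
        codon_table(self.codon_scheme)  # validates scheme
        for p, codon in self.fixed_codons.items():
            if translate(codon) != self.template_peptide[p - 1]:
                raise ValueError(
                    f"fixed codon {codon} at position {p} does not encode "
                    f"template residue {self.template_peptide[p - 1]}"
                )

    @property
    def length(self) -> int:
        return len(self.template_peptide)

    @property
    def template_string(self) -> str:
        return "".join(
            "X" if i + 1 in self.diversified_positions else a
            for i, a in enumerate(self.template_peptide)
        )

    @property
    def oligo(self) -> str:
        parts = []
        for i, a in enumerate(self.template_peptide):
            pos = i + 1
            if pos in self.diversified_positions:
                parts.append(self.codon_scheme)
            else:
                parts.append(self.fixed_codons.get(pos, PREFERRED_CODON[a]))
        return "".join(parts)


def design_library(
    template_peptide: str,
    diversified_positions: Iterable[int],
    codon_scheme: str = "NNK",
    fixed_codons: Optional[Mapping[int, str]] = None,
) -> LibraryDesign:
    """Build a :class:`LibraryDesign`; positions are 1-based."""
    return LibraryDesign(
        template_peptide=template_peptide,
        diversified_positions=frozenset(diversified_positions),
        codon_scheme=codon_scheme,
        fixed_codons=dict(fixed_codons or {}),
    )


class DiversityReport(NamedTuple):
    nt_variants: int
    stop_free_peptides: int
    stop_containing_fraction: float


def diversity(design: LibraryDesign) -> DiversityReport:
    """Theoretical library diversity over the diversified positions."""
    table = codon_table(design.codon_scheme)
    k = len(design.diversified_positions)
    n_codons = len(table)
    n_stop = sum(1 for aa in table.values() if aa == "*")
    n_aa = len({aa for aa in table.values() if aa != "*"})
    return DiversityReport(
        nt_variants=n_codons**k,
        stop_free_peptides=n_aa**k,
        stop_containing_fraction=1.0 - ((n_codons - n_stop) / n_codons) ** k,
    )


# ---------------------------------------------------------------------------
# Read merging and peptide-region extraction
# ---------------------------------------------------------------------------


class MergeResult(NamedTuple):
    seq: Optional[str]
    qual: Optional[str]
    reason: Optional[str]  # None | "no_overlap" | "ambiguous"


def _overlap_match_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """matches[o] (o = 1..min(n1,n2)) for suffix-of-a vs prefix-of-b overlaps."""
    n1, n2 = len(a), len(b)
    total = np.zeros(n1 + n2 - 1)
    for base in (65, 67, 71, 84):  # A C G T
        total += np.correlate((a == base).astype(float), (b == base).astype(float), "full")
    m = min(n1, n2)
    # overlap o aligns a[n1-o+i] with b[i]; full-mode index n1 + n2 - 1 - o.
    idx = n1 + n2 - 1 - np.arange(1, m + 1)
    return np.rint(total[idx]).astype(int)  # matches[o-1]


def merge_pairs(
    r1: str,
    r2: str,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.25,
    q1: Optional[str] = None,
    q2: Optional[str] = None,
) -> MergeResult:
    """Merge a read pair by its best 3'-overlap.

    ``r2`` is supplied as sequenced and reverse-complemented internally.
    Candidate overlaps of length >= ``min_overlap`` qualify when their
    mismatch fraction is <= ``max_mismatch_frac``; the best overlap maximises
    matches - mismatches, with two equally good candidates reported as
    ambiguous.  Disagreeing overlap bases are resolved to the higher-quality
    base, ties to r1.
    """
    b = reverse_complement(r2)
    qb = q2[::-1] if q2 is not None else None
    a = r1
    n1, n2 = len(a), len(b)
    if min(n1, n2) < min_overlap or min_overlap < 1:
        return MergeResult(None, None, "no_overlap")
    a_arr = np.frombuffer(a.encode(), np.uint8)
    b_arr = np.frombuffer(b.encode(), np.uint8)
    matches = _overlap_match_counts(a_arr, b_arr)
    overlaps = np.arange(1, min(n1, n2) + 1)
    mism = overlaps - matches
    ok = (overlaps >= min_overlap) & (mism <= max_mismatch_frac * overlaps)
    if not ok.any():
        return MergeResult(None, None, "no_overlap")
    score = np.where(ok, matches - mism, np.iinfo(np.int64).min)
    best = int(score.max())
    if int((score == best).sum()) > 1:
        return MergeResult(None, None, "ambiguous")
    o = int(overlaps[int(score.argmax())])

    ov_a = a[n1 - o:]
    ov_b = b[:o]
    if ov_a == ov_b:
        consensus = ov_a
        cons_q = None if q1 is None else "".join(
            max(x, y) for x, y in zip(q1[n1 - o:], qb or q1[n1 - o:])
        )
    else:
        chars = []
        quals = []
        for i in range(o):
            ca, cb = ov_a[i], ov_b[i]
            qa = q1[n1 - o + i] if q1 is not None else "I"
            qv = qb[i] if qb is not None else "I"
            if ca == cb or qa >= qv:
                chars.append(ca)
                quals.append(max(qa, qv) if ca == cb else qa)
            else:
                chars.append(cb)
                quals.append(qv)
        consensus = "".join(chars)
        cons_q = "".join(quals)
    seq = a[: n1 - o] + consensus + b[o:]
    if q1 is not None and qb is not None:
        qual = q1[: n1 - o] + (cons_q or "") + qb[o:]
    else:
        qual = None
    return MergeResult(seq, qual, None)


class RegionResult(NamedTuple):
    seq: Optional[str]
    reason: Optional[str]  # None | "no_anchor" | "length"


def extract_region(
    merged: str,
    flank_5: str,
    flank_3: str,
    max_mm: int = 1,
    expected_length: Optional[int] = None,
) -> RegionResult:
    """Extract the insert strictly between two anchor sequences.

    Each anchor must match within ``max_mm`` edits (edlib infix alignment);
    when ``expected_length`` is given the insert must have exactly that
    length (3 x template length for a peptide-coding region).
    """
    import edlib

    if not flank_5 or not flank_3:
        raise ValueError("anchors must be non-empty")
    hit5 = edlib.align(flank_5, merged, mode="HW", task="locations", k=max_mm)
    if hit5["editDistance"] < 0:
        return RegionResult(None, "no_anchor")
    end5 = hit5["locations"][0][1]  # inclusive
    tail_start = end5 + 1
    hit3 = edlib.align(flank_3, merged[tail_start:], mode="HW", task="locations", k=max_mm)
    if hit3["editDistance"] < 0:
        return RegionResult(None, "no_anchor")
    start3 = tail_start + hit3["locations"][0][0]
    region = merged[tail_start:start3]
    if expected_length is not None and len(region) != expected_length:
        return RegionResult(None, "length")
    return RegionResult(region, None)


def translate_filter(nt: str, design: LibraryDesign) -> tuple[Optional[str], Optional[str]]:
    """Translate a peptide-coding insert and apply the template filter.

    Accepts iff there is no stop codon and every non-diversified position
    translates to the template residue.  Returns ``(peptide, None)`` or
    ``(None, reason)`` with reason in {"stop", "template_mismatch"}.
    """
    if len(nt) != 3 * design.length:
        raise ValueError(f"insert length {len(nt)} != 3x template length {3 * design.length}")
    aa = translate(nt)
    if "*" in aa:
        return None, "stop"
    for i, a in enumerate(aa):
        if i + 1 not in design.diversified_positions and a != design.template_peptide[i]:
            return None, "template_mismatch"
    return aa, None


# ---------------------------------------------------------------------------
# Count tables, preference matrices, trajectories
# ---------------------------------------------------------------------------


@dataclass
class PeptideCountTable:
    """Peptide read counts for one selection round of one TCR campaign."""

    round_index: int
    counts: dict[str, int]
    tcr_label: str = ""

    def __post_init__(self) -> None:
        lengths = {len(p) for p in self.counts}
        if len(lengths) > 1:
            raise ValueError("peptides must have uniform length")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("counts must be >= 1")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def tally_peptides(
    peptides: Iterable[str],
    round_index: int = 0,
    tcr_label: str = "",
    absorb_singletons: bool = False,
    absorb_ratio: int = 10,
) -> PeptideCountTable:
    """Exact-identity peptide counts (CD-HIT clustering stand-in).

    With ``absorb_singletons`` a count-1 peptide within one amino-acid
    mismatch of a peptide at >= ``absorb_ratio``-fold higher count is folded
    into that neighbour (largest neighbour wins, ties lexicographic).
    """
    counts = Counter(peptides)
    if absorb_singletons and counts:
        singles = [p for p, c in counts.items() if c == 1]
        for p in singles:
            # choose the neighbour with max count, tie -> lexicographically smallest
            candidates = []
            for i in range(len(p)):
                for a in AA_ORDER:
                    if a == p[i]:
                        continue
                    q = p[:i] + a + p[i + 1:]
                    c = counts.get(q, 0)
                    if c >= absorb_ratio:
                        candidates.append((-c, q))
            if candidates:
                _, target = min(candidates)
                counts[target] += counts.pop(p)
    return PeptideCountTable(round_index=round_index, counts=dict(counts), tcr_label=tcr_label)


@dataclass
class PositionPreferenceMatrix:
    """Read-count-weighted amino-acid frequency per peptide position."""

    length: int
    weights: "np.ndarray"  # shape (length, 20), rows sum to 1

    def weight(self, position: int, aa: str) -> float:
        """Weight of amino acid ``aa`` at 1-based ``position``."""
        return float(self.weights[position - 1, AA_ORDER.index(aa)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.weights, index=range(1, self.length + 1), columns=list(AA_ORDER)
        )


def preference_matrix(
    table: PeptideCountTable, design: Optional[LibraryDesign] = None
) -> PositionPreferenceMatrix:
    """Positional amino-acid prevalence weighted by read count."""
    if not table.counts:
        raise ValueError("empty count table")
    peptides = list(table.counts)
    L = len(peptides[0])
    if design is not None and L != design.length:
        raise ValueError("peptide length does not match design template")
    arr = np.frombuffer("".join(peptides).encode(), np.uint8).reshape(len(peptides), L)
    w = np.asarray([table.counts[p] for p in peptides], dtype=float)
    aa_codes = np.frombuffer(AA_ORDER.encode(), np.uint8)
    out = np.zeros((L, len(AA_ORDER)))
    for j in range(L):
        col = arr[:, j]
        for k, code in enumerate(aa_codes):
            out[j, k] = w[col == code].sum()
    out /= out.sum(axis=1, keepdims=True)
    return PositionPreferenceMatrix(length=L, weights=out)


def pooled_counts(tables: Sequence[PeptideCountTable]) -> PeptideCountTable:
    """Pool several rounds into one count table (round_index of the last)."""
    counts: Counter[str] = Counter()
    for t in tables:
        counts.update(t.counts)
    return PeptideCountTable(
        round_index=tables[-1].round_index, counts=dict(counts), tcr_label=tables[-1].tcr_label
    )


@dataclass
class MimotopeCandidate:
    peptide: str
    final_round_frequency: float
    cumulative_fold_enrichment: float
    trajectory: list[float]  # per-round pseudocount-adjusted frequency
    fold_changes: list[float]  # round-over-round frequency ratios


def _safe_ratio(cur: float, prev: float) -> float:
    """Frequency ratio; with pseudocount 0 an appearance from zero is inf."""
    if prev > 0:
        return cur / prev
    return float("inf") if cur > 0 else 1.0


def enrichment_trajectory(
    tables: Sequence[PeptideCountTable], pseudocount: float = 1.0
) -> dict[str, MimotopeCandidate]:
    """Per-peptide per-round frequencies and fold changes across rounds.

    freq_t(p) = (count_t(p) + pseudocount) / (depth_t + pseudocount * U)
    with U the union of peptides over all rounds, so unobserved peptides get
    a finite frequency and folds stay defined.
    """
    if len(tables) < 2:
        raise ValueError("need at least two selection rounds")
    union = sorted(set().union(*(t.counts.keys() for t in tables)))
    U = len(union)
    denoms = [t.depth + pseudocount * U for t in tables]
    freqs = {}
    for p in union:
        traj = [
            (t.counts.get(p, 0) + pseudocount) / d
            for t, d in zip(tables, denoms)
        ]
        folds = [_safe_ratio(traj[i], traj[i - 1]) for i in range(1, len(traj))]
        freqs[p] = MimotopeCandidate(
            peptide=p,
            final_round_frequency=traj[-1],
            cumulative_fold_enrichment=_safe_ratio(traj[-1], traj[0]),
            trajectory=traj,
            fold_changes=folds,
        )
    return freqs


def rank_mimotopes(
    trajectories: Mapping[str, MimotopeCandidate] | Iterable[MimotopeCandidate],
) -> list[MimotopeCandidate]:
    """Rank candidates by cumulative fold enrichment.

    Ties break by final-round frequency (descending), then peptide sequence.
    """
    cands = (
        list(trajectories.values())
        if isinstance(trajectories, Mapping)
        else list(trajectories)
    )
    return sorted(
        cands,
        key=lambda c: (-c.cumulative_fold_enrichment, -c.final_round_frequency, c.peptide),
    )
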