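"""Plate-barcoded paired TCR amplicon processing.

Turns paired-end amplicon reads -- each carrying group/plate/row/column
well barcodes from nested single-cell RT-PCR -- into paired alpha/beta
clonotypes: merge mates, demultiplex by barcode, segregate chains on the
constant region, collapse sequencing errors, annotate V/J usage and the
CDR3 junction, pair chains per well, and group cells into clonal lineages.

Coordinates are 0-based half-open internally; the CDR3 spans the conserved
V-region cysteine through the J-region anchor residue, both included.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .germline import GermlineReference, GermlineSegment, translate
from .library import merge_pairs

__all__ = [
    "Read",
    "BarcodeScheme",
    "BarcodeCollisionError",
    "UnannotatableError",
    "ChainAnnotation",
    "CellRecord",
    "Clonotype",
    "ClonalitySummary",
    "default_scheme",
    "demultiplex",
    "assign_chain",
    "collapse_reads",
    "annotate_vj",
    "extract_cdr3",
    "pair_well",
    "call_clonotypes",
    "flag_contaminants",
    "clonality",
    "process_plate",
    "PlateResult",
]


@dataclass(frozen=True)
class Read:
    id: str
    seq: str
    qual: Optional[str] = None


class BarcodeCollisionError(ValueError):
    """Barcodes within a field are too close to demultiplex safely."""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeScheme:
    """Well-barcode layout for plate demultiplexing.

    Each field maps label -> equal-length barcode; ``layout`` orders the
    fields as they appear at the start of read 1.  Within a field barcodes
    must be pairwise Hamming distance >= 2 (ambiguity at equal distance is
    then resolved by the unique-best rule).
    """

    group_barcodes: dict[str, str]
    plate_barcodes: dict[str, str]
    column_barcodes: dict[str, str]
    row_barcodes: dict[str, str]
    layout: tuple[str, ...] = ("group", "plate", "row", "column")
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if sorted(self.layout) != sorted(("group", "plate", "row", "column")):
            raise ValueError("layout must order the four barcode fields")
        for name in self.layout:
            codes = self.field(name)
            if not codes:
                raise BarcodeCollisionError(f"{name}: empty barcode set")
            lengths = {len(c) for c in codes.values()}
            if len(lengths) != 1:
                raise BarcodeCollisionError(f"{name}: barcodes must be equal length")
            items = list(codes.values())
            for i in range(len(items)):
                for j in range(i + 1, len(items)):
                    if hamming(items[i], items[j]) < 2:
                        raise BarcodeCollisionError(
                            f"{name}: barcodes {items[i]} and {items[j]} "
                            "are <2 mismatches apart"
                        )

    def field(self, name: str) -> dict[str, str]:
        return getattr(self, f"{name}_barcodes")

    @property
    def field_lengths(self) -> dict[str, int]:
        return {n: len(next(iter(self.field(n).values()))) for n in self.layout}

    @property
    def prefix_length(self) -> int:
        return sum(self.field_lengths.values())

    def well_order(self) -> tuple[str, ...]:
        """Canonical well-id ordering: (group, plate, row, column)."""
        return ("group", "plate", "row", "column")


def default_scheme(
    n_groups: int = 2,
    n_plates: int = 4,
    n_rows: int = 8,
    n_columns: int = 12,
    length: int = 8,
    min_distance: int = 3,
) -> BarcodeScheme:
    """A deterministic barcode scheme with pairwise distance >= min_distance."""
    rng = np.random.default_rng(987654321)
    bases = np.array(list("ACGT"))

    def make(n: int) -> list[str]:
        out: list[str] = []
        while len(out) < n:
            cand = "".join(rng.choice(bases, length))
            if all(hamming(cand, c) >= min_distance for c in out):
                out.append(cand)
        return out

    groups = make(n_groups)
    plates = make(n_plates)
    rows = make(n_rows)
    cols = make(n_columns)
    row_labels = [chr(ord("A") + i) for i in range(n_rows)]
    return BarcodeScheme(
        group_barcodes={f"g{i + 1}": b for i, b in enumerate(groups)},
        plate_barcodes={f"p{i + 1}": b for i, b in enumerate(plates)},
        row_barcodes={lab: b for lab, b in zip(row_labels, rows)},
        column_barcodes={str(i + 1): b for i, b in enumerate(cols)},
    )


def _match_field(observed: str, codes: Mapping[str, str], max_mismatch: int):
    """Unique-best barcode match; returns (label, None) or (None, reason)."""
    dists = sorted((hamming(bc, observed), label) for label, bc in codes.items())
    best_d, best_label = dists[0]
    if best_d > max_mismatch:
        return None, "no_match"
    if len(dists) > 1 and dists[1][0] == best_d:
        return None, "ambiguous"
    return best_label, None


def demultiplex(
    reads: Iterable[Read], scheme: BarcodeScheme
) -> tuple[dict[tuple[str, str, str, str], list[Read]], list[tuple[Read, str]]]:
    """Assign reads to wells by their barcode prefix.

    A read is assigned iff every field has a unique best match within
    ``scheme.max_mismatch``; otherwise it lands in the unassigned bin with a
    reason ("too_short", "no_match", "ambiguous").  Well ids are
    (group, plate, row, column) label tuples.
    """
    lengths = scheme.field_lengths
    assigned: dict[tuple[str, str, str, str], list[Read]] = defaultdict(list)
    unassigned: list[tuple[Read, str]] = []
    for read in reads:
        if len(read.seq) < scheme.prefix_length:
            unassigned.append((read, "too_short"))
            continue
        pos = 0
        labels: dict[str, str] = {}
        reason = None
        for name in scheme.layout:
            seg = read.seq[pos: pos + lengths[name]]
            pos += lengths[name]
            label, why = _match_field(seg, scheme.field(name), scheme.max_mismatch)
            if label is None:
                reason = why
                break
            labels[name] = label
        if reason is not None:
            unassigned.append((read, reason))
        else:
            well = tuple(labels[n] for n in scheme.well_order())
            assigned[well].append(read)
    return dict(assigned), unassigned


def assign_chain(
    seq: str,
    constant_refs: Mapping[str, str],
    max_distance_frac: float = 0.25,
    margin: int = 3,
) -> str:
    """Classify a read as alpha/beta by its constant-region match.

    The chain whose constant reference aligns (edlib infix) with the fewest
    edits wins, provided the distance is within ``max_distance_frac`` of the
    reference length and beats the other chain by >= ``margin`` edits.
    """
    import edlib

    dists = {}
    for chain, ref in constant_refs.items():
        k = int(max_distance_frac * len(ref))
        d = edlib.align(ref, seq, mode="HW", k=k)["editDistance"]
        dists[chain] = d if d >= 0 else k + margin + 1
    if len(dists) < 2:
        raise ValueError("need constant references for both chains")
    (c1, d1), (c2, d2) = sorted(dists.items(), key=lambda kv: kv[1])[:2]
    if d1 > max_distance_frac * len(constant_refs[c1]):
        return "unknown"
    if d2 - d1 < margin:
        return "unknown"
    return c1


def collapse_reads(
    seqs: Sequence[str],
    ratio_threshold: float = 5.0,
    max_mm: int = 1,
) -> list[tuple[str, int]]:
    """Collapse unique sequences by frequency-ratio absorption.

    A unique sequence is absorbed when another sequence with strictly
    greater multiplicity, within ``max_mm`` mismatches, outnumbers it by
    >= ``ratio_threshold`` (original multiplicities).  Support follows the
    largest qualifying absorber (ties lexicographic) transitively.
    Length-discordant sequences form separate classes.  Survivors are
    returned sorted by support descending, then sequence.
    """
    if not seqs:
        return []
    by_len: dict[int, Counter] = defaultdict(Counter)
    for s in seqs:
        by_len[len(s)][s] += 1
    support: dict[str, int] = {}
    absorbed_into: dict[str, str] = {}
    for counts in by_len.values():
        # ascending by count so absorption chains resolve upward
        for s in sorted(counts, key=lambda x: (counts[x], x)):
            c = counts[s]
            candidates = [
                t
                for t in counts
                if counts[t] > c
                and counts[t] >= ratio_threshold * c
                and hamming(s, t) <= max_mm
            ]
            if candidates:
                target = max(candidates, key=lambda t: (counts[t], [-ord(ch) for ch in t]))
                while target in absorbed_into:
                    target = absorbed_into[target]
                absorbed_into[s] = target
                support[target] = support.get(target, counts[target]) + support.pop(s, c)
            else:
                support.setdefault(s, c)
    return sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))


class UnannotatableError(ValueError):
    """No germline segment aligned above the minimum score."""

    def __init__(self, message: str, v_best: Optional[tuple] = None, j_best: Optional[tuple] = None):
        super().__init__(message)
        self.v_best = v_best
        self.j_best = j_best


@dataclass
class ChainAnnotation:
    """V/J gene calls and CDR3 junction for one chain consensus."""

    chain: str  # "alpha" | "beta"
    v_call: str
    j_call: str
    d_call: Optional[str]
    v_score: float
    j_score: float
    cdr3_nt: Optional[str]
    cdr3_aa: Optional[str]
    productive: bool
    nt: str = ""
    consensus_count: int = 1


def _make_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _best_segment(aligner, nt: str, segments: Sequence[GermlineSegment]):
    scored = sorted(
        ((float(aligner.score(nt, s.nt)), s.name) for s in segments),
        key=lambda x: (-x[0], x[1]),
    )
    return scored[0]


def _ref_to_read(aligner, nt: str, seg: GermlineSegment, ref_pos: int) -> Optional[int]:
    aln = aligner.align(nt, seg.nt)[0]
    read_blocks, ref_blocks = aln.aligned
    for (rs, re), (fs, fe) in zip(read_blocks, ref_blocks):
        if fs <= ref_pos < fe:
            return rs + (ref_pos - fs)
    return None


def extract_cdr3(nt: str, cys_start: int, anchor_start: int) -> tuple[str, str, bool]:
    """CDR3 from the conserved Cys codon through the J anchor codon.

    Returns ``(cdr3_nt, cdr3_aa, productive)``; a frame break or internal
    stop clears the productive flag but the translatable prefix is still
    reported.
    """
    cdr3_nt = nt[cys_start: anchor_start + 3]
    cdr3_aa = translate(cdr3_nt)
    productive = len(cdr3_nt) % 3 == 0 and "*" not in cdr3_aa and len(cdr3_nt) > 0
    return cdr3_nt, cdr3_aa, productive


def annotate_vj(
    nt: str,
    ref: GermlineReference,
    chain: str,
    v_min_score: float = 30.0,
    j_min_score: float = 14.0,
) -> ChainAnnotation:
    """Best-scoring local V and J alignment with CDR3 extraction.

    Ties between segments break by score then name.  If neither segment
    kind reaches its minimum score an :class:`UnannotatableError` carrying
    the best partial scores is raised.
    """
    locus = {"alpha": "TRA", "beta": "TRB"}[chain]
    v_segs = ref.by_kind(locus, "V")
    j_segs = ref.by_kind(locus, "J")
    if not v_segs or not j_segs:
        raise ValueError(f"reference lacks V or J segments for {locus}")
    aligner = _make_aligner()
    v_score, v_name = _best_segment(aligner, nt, v_segs)
    j_score, j_name = _best_segment(aligner, nt, j_segs)
    if v_score < v_min_score or j_score < j_min_score:
        raise UnannotatableError(
            f"no segment above minimum score (best V {v_name}={v_score}, "
            f"best J {j_name}={j_score})",
            v_best=(v_name, v_score),
            j_best=(j_name, j_score),
        )
    v_seg = ref.get(v_name)
    j_seg = ref.get(j_name)
    cys = _ref_to_read(aligner, nt, v_seg, v_seg.conserved_cys_offset)
    anchor = _ref_to_read(aligner, nt, j_seg, j_seg.j_anchor_offset)
    if cys is None or anchor is None or anchor <= cys:
        cdr3_nt, cdr3_aa, productive = None, None, False
    else:
        cdr3_nt, cdr3_aa, productive = extract_cdr3(nt, cys, anchor)
    return ChainAnnotation(
        chain=chain,
        v_call=v_name,
        j_call=j_name,
        d_call=None,
        v_score=v_score,
        j_score=j_score,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        productive=productive,
        nt=nt,
    )


@dataclass
class CellRecord:
    """The per-well outcome of chain pairing."""

    well_id: tuple
    alpha: Optional[ChainAnnotation]
    beta: Optional[ChainAnnotation]
    status: str  # paired | alpha_only | beta_only | multiplet | empty
    sample: str = ""


def pair_well(
    well_id: tuple,
    consensuses: Mapping[str, Sequence[tuple[str, int]]],
    annotate: Callable[[str, str], ChainAnnotation],
    dominance_threshold: float = 10.0,
    sample: str = "",
) -> CellRecord:
    """Pair the alpha/beta consensuses of one well into a cell record.

    One consensus per chain pairs directly; with several, the dominant one
    is used when its support exceeds the runner-up ``dominance_threshold``-
    fold, otherwise the well is a multiplet.  Consensuses that fail V/J
    annotation are treated as absent.
    """
    chosen: dict[str, Optional[ChainAnnotation]] = {"alpha": None, "beta": None}
    multiplet = False
    for chain in ("alpha", "beta"):
        items = sorted(consensuses.get(chain, []), key=lambda x: (-x[1], x[0]))
        if not items:
            continue
        if len(items) > 1 and items[0][1] < dominance_threshold * items[1][1]:
            multiplet = True
            continue
        nt, count = items[0]
        try:
            ann = annotate(nt, chain)
        except UnannotatableError:
            continue
        ann.consensus_count = count
        chosen[chain] = ann
    if multiplet:
        status = "multiplet"
    elif chosen["alpha"] and chosen["beta"]:
        status = "paired"
    elif chosen["alpha"]:
        status = "alpha_only"
    elif chosen["beta"]:
        status = "beta_only"
    else:
        status = "empty"
    return CellRecord(
        well_id=well_id, alpha=chosen["alpha"], beta=chosen["beta"],
        status=status, sample=sample,
    )


@dataclass
class Clonotype:
    """A paired alpha/beta clonal lineage."""

    id: str
    cdr3_alpha_aa: str
    cdr3_beta_aa: str
    v_alpha: str
    j_alpha: str
    v_beta: str
    j_beta: str
    d_beta: Optional[str]
    size: int
    sample: str
    member_wells: list
    cdr3_alpha_nt: str = ""
    cdr3_beta_nt: str = ""


def call_clonotypes(cells: Sequence[CellRecord], level: str = "aa") -> list[Clonotype]:
    """Group paired cells into clonal lineages.

    The lineage key is (CDR3a, Va, Ja, CDR3b, Vb, Jb) at the amino-acid
    level by default (``level="nt"`` groups on nucleotide CDR3s).  Output is
    sorted by size descending, then key.
    """
    if level not in ("aa", "nt"):
        raise ValueError("level must be 'aa' or 'nt'")
    groups: dict[tuple, list[CellRecord]] = defaultdict(list)
    for cell in cells:
        if cell.status != "paired":
            continue
        a, b = cell.alpha, cell.beta
        cdr3a = a.cdr3_aa if level == "aa" else a.cdr3_nt
        cdr3b = b.cdr3_aa if level == "aa" else b.cdr3_nt
        key = (cdr3a or "", a.v_call, a.j_call, cdr3b or "", b.v_call, b.j_call)
        groups[key].append(cell)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    out = []
    for i, (key, members) in enumerate(ordered, start=1):
        first = members[0]
        samples = sorted({m.sample for m in members if m.sample})
        out.append(
            Clonotype(
                id=f"clone_{i:04d}",
                cdr3_alpha_aa=first.alpha.cdr3_aa or "",
                cdr3_beta_aa=first.beta.cdr3_aa or "",
                v_alpha=first.alpha.v_call,
                j_alpha=first.alpha.j_call,
                v_beta=first.beta.v_call,
                j_beta=first.beta.j_call,
                d_beta=first.beta.d_call,
                size=len(members),
                sample=",".join(samples),
                member_wells=[m.well_id for m in members],
                cdr3_alpha_nt=first.alpha.cdr3_nt or "",
                cdr3_beta_nt=first.beta.cdr3_nt or "",
            )
        )
    return out


def flag_contaminants(
    clonotypes: Sequence[Clonotype],
    blacklist_nt: set[str] = frozenset(),
    empty_well_seqs: set[str] = frozenset(),
) -> dict[str, bool]:
    """Exact nucleotide-level contamination screen.

    A clonotype is flagged iff a chain CDR3 nucleotide sequence exactly
    matches a blacklisted sequence (earlier runs) or a sequence seen in
    intentionally empty wells.  Near-matches are NOT flagged.
    """
    bad = set(blacklist_nt) | set(empty_well_seqs)
    return {
        c.id: (c.cdr3_alpha_nt in bad or c.cdr3_beta_nt in bad)
        for c in clonotypes
    }


@dataclass
class ClonalitySummary:
    total_cells: int
    fractions: dict[str, float]  # clonotype id -> fraction of cells
    top_k: int
    top_k_cumulative_fraction: float


def clonality(clonotypes: Sequence[Clonotype], k: int = 3) -> ClonalitySummary:
    """Per-clone cell fractions and top-k cumulative fraction."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not clonotypes:
        raise ValueError("no clonotypes")
    total = sum(c.size for c in clonotypes)
    fractions = {c.id: c.size / total for c in clonotypes}
    top = sorted(fractions.values(), reverse=True)[:k]
    return ClonalitySummary(
        total_cells=total,
        fractions=fractions,
        top_k=k,
        top_k_cumulative_fraction=float(sum(top)),
    )


# ---------------------------------------------------------------------------
# End-to-end plate processing
# ---------------------------------------------------------------------------


@dataclass
class PlateResult:
    cells: list[CellRecord]
    clonotypes: list[Clonotype]
    n_pairs: int
    n_merged: int
    n_assigned: int
    unassigned_reasons: Counter
    merge_failures: Counter


def process_plate(
    read_pairs: Sequence,
    scheme: BarcodeScheme,
    reference: GermlineReference,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.25,
    ratio_threshold: float = 5.0,
    max_mm: int = 1,
    dominance_threshold: float = 10.0,
    clonotype_level: str = "aa",
    sample: str = "",
) -> PlateResult:
    """Merge, demultiplex, collapse, annotate, pair, and call clonotypes.

    ``read_pairs`` yield ``(id, r1_seq, r1_qual, r2_seq, r2_qual)``
    (quality may be None).
    """
    constant_refs = reference.constant_refs()
    merged_reads: list[Read] = []
    merge_failures: Counter = Counter()
    n_pairs = 0
    for rp in read_pairs:
        rid, r1, q1, r2, q2 = rp
        n_pairs += 1
        m = merge_pairs(r1, r2, min_overlap=min_overlap,
                        max_mismatch_frac=max_mismatch_frac, q1=q1, q2=q2)
        if m.seq is None:
            merge_failures[m.reason] += 1
        else:
            merged_reads.append(Read(rid, m.seq, m.qual))
    assigned, unassigned = demultiplex(merged_reads, scheme)
    unassigned_reasons = Counter(r for _, r in unassigned)
    prefix = scheme.prefix_length

    def annotator(nt: str, chain: str) -> ChainAnnotation:
        return annotate_vj(nt, reference, chain)

    cells = []
    for well in sorted(assigned):
        by_chain: dict[str, list[str]] = defaultdict(list)
        for read in assigned[well]:
            body = read.seq[prefix:]
            chain = assign_chain(body, constant_refs)
            if chain != "unknown":
                by_chain[chain].append(body)
        consensuses = {
            chain: collapse_reads(seqs, ratio_threshold=ratio_threshold, max_mm=max_mm)
            for chain, seqs in by_chain.items()
        }
        cells.append(
            pair_well(well, consensuses, annotator,
                      dominance_threshold=dominance_threshold, sample=sample)
        )
    clonotypes = call_clonotypes(cells, level=clonotype_level)
    return PlateResult(
        cells=cells,
        clonotypes=clonotypes,
        n_pairs=n_pairs,
        n_merged=len(merged_reads),
        n_assigned=sum(len(v) for v in assigned.values()),
        unassigned_reasons=unassigned_reasons,
        merge_failures=merge_failures,
    )
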