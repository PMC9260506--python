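"""Germline V/(D)/J/C segment references for TCR amplicon annotation.

A :class:`GermlineReference` holds the segment sequences the repertoire
pipeline aligns reads against.  Segments follow rearrangement conventions:
every V segment carries an in-frame conserved cysteine codon near its 3'
end (the first residue of the CDR3), and every J segment carries an anchor
residue followed by a G-x-G pattern (the last residue of the CDR3).  The
anchor is phenylalanine or tryptophan for almost all segments; TRAJ7 -- an
ORF segment that is nonetheless productively used by p15E-reactive public
clones -- anchors on leucine.

The packaged reference is synthetic: segment bodies are invented, but the
junction-proximal residues of the named core segments (TRAV10, TRAJ7,
TRBV5, ...) are chosen so that the CDR3s of the p15E-reactive public
clonotype panel can be reconstructed exactly.  User-supplied references can
be imported from FASTA with :meth:`GermlineReference.from_fasta`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio.Seq import Seq

__all__ = [
    "GermlineSegment",
    "GermlineReference",
    "PREFERRED_CODON",
    "encode_peptide",
    "translate",
    "J_ANCHOR_RESIDUES",
]

# Mouse-frequent codon per amino acid, used wherever a deterministic
# reverse translation is needed (fixed library positions, fixture CDR3s).
PREFERRED_CODON = {
    "A": "GCC", "C": "TGT", "D": "GAC", "E": "GAG", "F": "TTT",
    "G": "GGA", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "AGA",
    "S": "TCT", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

#: Residues accepted as the J-segment anchor (F/W canonically; L for ORF
#: segments such as TRAJ7).
J_ANCHOR_RESIDUES = frozenset("FWL")


def encode_peptide(aa: str) -> str:
    """Deterministically reverse-translate ``aa`` using preferred codons."""
    try:
        return "".join(PREFERRED_CODON[a] for a in aa)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot encode residue {exc}") from exc


def translate(nt: str) -> str:
    """Translate ``nt`` (trailing partial codon ignored)."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


@dataclass(frozen=True)
class GermlineSegment:
    """One germline gene segment.

    ``conserved_cys_offset`` (V segments) and ``j_anchor_offset`` (J
    segments) are 0-based nucleotide offsets of the first base of the
    conserved cysteine / anchor codon.
    """

    name: str
    locus: str  # "TRA" | "TRB"
    kind: str   # "V" | "D" | "J" | "C"
    nt: str
    conserved_cys_offset: Optional[int] = None
    j_anchor_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.locus not in ("TRA", "TRB"):
            raise ValueError(f"unknown locus {self.locus!r}")
        if self.kind not in "VDJC":
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "V":
            off = self.conserved_cys_offset
            if off is None or off % 3 != 0 or self.nt[off:off + 3] not in ("TGT", "TGC"):
                raise ValueError(f"{self.name}: no in-frame conserved Cys codon at offset {off}")
        if self.kind == "J":
            off = self.j_anchor_offset
            if off is None:
                raise ValueError(f"{self.name}: J segment needs j_anchor_offset")
            aa = translate(self.nt[off:])
            if not aa or aa[0] not in J_ANCHOR_RESIDUES:
                raise ValueError(f"{self.name}: anchor residue {aa[:1]!r} not in {sorted(J_ANCHOR_RESIDUES)}")
            if len(aa) < 4 or aa[1] != "G" or aa[3] != "G":
                raise ValueError(f"{self.name}: no G-x-G pattern after anchor")

    @property
    def v_tail_aa(self) -> str:
        """Translation of a V segment from its conserved Cys to its end."""
        if self.kind != "V":
            raise ValueError("v_tail_aa only defined for V segments")
        return translate(self.nt[self.conserved_cys_offset:])

    @property
    def j_cdr3_aa(self) -> str:
        """Translation of a J segment up to and including the anchor."""
        if self.kind != "J":
            raise ValueError("j_cdr3_aa only defined for J segments")
        return translate(self.nt[: self.j_anchor_offset + 3])


class GermlineReference:
    """A collection of uniquely named germline segments."""

    def __init__(self, segments: Iterable[GermlineSegment]):
        self.segments = list(segments)
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        self._by_name = {s.name: s for s in self.segments}

    def __len__(self) -> int:
        return len(self.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GermlineReference):
            return NotImplemented
        return self.segments == other.segments

    def get(self, name: str) -> GermlineSegment:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no segment named {name!r} in reference") from None

    def by_kind(self, locus: str, kind: str) -> list[GermlineSegment]:
        return [s for s in self.segments if s.locus == locus and s.kind == kind]

    def constant_refs(self) -> dict[str, str]:
        """Mapping chain -> constant-region nucleotide sequence."""
        out = {}
        for chain, locus in (("alpha", "TRA"), ("beta", "TRB")):
            segs = self.by_kind(locus, "C")
            if segs:
                out[chain] = segs[0].nt
        return out

    # --- FASTA round-trip -------------------------------------------------
    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.segments:
                meta = [f"locus={s.locus}", f"kind={s.kind}"]
                if s.conserved_cys_offset is not None:
                    meta.append(f"cys={s.conserved_cys_offset}")
                if s.j_anchor_offset is not None:
                    meta.append(f"anchor={s.j_anchor_offset}")
                fh.write(f">{s.name} {' '.join(meta)}\n{s.nt}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GermlineReference":
        from Bio import SeqIO

        segments = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = dict(
                kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
            )
            segments.append(
                GermlineSegment(
                    name=rec.id,
                    locus=fields["locus"],
                    kind=fields["kind"],
                    nt=str(rec.seq).upper(),
                    conserved_cys_offset=int(fields["cys"]) if "cys" in fields else None,
                    j_anchor_offset=int(fields["anchor"]) if "anchor" in fields else None,
                )
            )
        return cls(segments)


# ---------------------------------------------------------------------------
# Core packaged segments.  Bodies are synthetic; the junction-proximal
# residues reconstruct the public-clone CDR3s (CAAK/CAAS... x CASS...).
# ---------------------------------------------------------------------------

_TRAV_BODIES = {
    "TRAV7-2": "GQSVEQHDGHNVMYRYE",
    "TRAV10": "GDSVTQMQGQVTLSEDT",
    "TRAV10D": "GDSVTQMEGPVTLSEES",
    "TRAV5D-4": "GEQVEQLPSILRVQEGS",
}
_TRBV_BODIES = {
    "TRBV2": "GAVVSQHPSWVISKSGT",
    "TRBV3": "GAVTQSPRNKVAVTGGK",
    "TRBV4": "GGIITQTPKFLIGQEGQ",
    "TRBV5": "GNTVTQSPESLIVPEGA",
    "TRBV16": "GDSVTQTEGPVTLPERA",
}
# J segments: CDR3-contributing residues through the anchor, then the
# FGxG-style tail that stays outside the CDR3.
_TRAJ_CORE = {
    # TRAJ7: ORF segment, leucine anchor; contributes DYSNNRLTL.
    "TRAJ7": ("DYSNNRLTL", "GKGT"),
}
_TRBJ_CORE = {
    "TRBJ1-1": ("NTEVFF", "GKGT"),
    "TRBJ1-2": ("NSDYTF", "GSGT"),
    "TRBJ2-1": ("NYAEQFF", "GPGT"),
    "TRBJ2-4": ("SQNTLYF", "GEGS"),
    "TRBJ2-5": ("NQDTQYF", "GPGT"),
    "TRBJ2-7": ("SYEQYF", "GPGT"),
}
_TRBD = {"TRBD1": "GGGACAGGGGGC", "TRBD2": "GGGACTGGGGGGGC"}
# Constant-region fragments covered by the nested amplicon (48 nt each).
_TRAC_NT = "ATACAGCCAGAAGCCACAGACTGGCTTGTACCAGCAGGATCTTGAAG"
_TRBC_NT = "GAGGATCTGAGAAATGTGACTCCACCCAAGGTCTCCTTGTTTGAGCCA"


def _v_segment(name: str, locus: str, body_aa: str, tail_aa: str) -> GermlineSegment:
    nt = encode_peptide(body_aa + tail_aa)
    return GermlineSegment(
        name=name, locus=locus, kind="V", nt=nt,
        conserved_cys_offset=3 * len(body_aa),
    )


def _j_segment(name: str, locus: str, cdr3_aa: str, tail_aa: str) -> GermlineSegment:
    nt = encode_peptide(cdr3_aa + tail_aa)
    return GermlineSegment(
        name=name, locus=locus, kind="J", nt=nt,
        j_anchor_offset=3 * (len(cdr3_aa) - 1),
    )


def core_segments() -> list[GermlineSegment]:
    """The fixed, seed-independent part of the packaged reference."""
    segs: list[GermlineSegment] = []
    for name, body in _TRAV_BODIES.items():
        segs.append(_v_segment(name, "TRA", body, "CAA"))
    for name, body in _TRBV_BODIES.items():
        segs.append(_v_segment(name, "TRB", body, "CASS"))
    for name, (cdr3, tail) in _TRAJ_CORE.items():
        segs.append(_j_segment(name, "TRA", cdr3, tail))
    for name, (cdr3, tail) in _TRBJ_CORE.items():
        segs.append(_j_segment(name, "TRB", cdr3, tail))
    for name, nt in _TRBD.items():
        segs.append(GermlineSegment(name=name, locus="TRB", kind="D", nt=nt))
    segs.append(GermlineSegment(name="TRAC", locus="TRA", kind="C", nt=_TRAC_NT))
    segs.append(GermlineSegment(name="TRBC", locus="TRB", kind="C", nt=_TRBC_NT))
    return segs
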