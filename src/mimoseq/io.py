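"""File I/O: FASTQ read pairs, AIRR-style TSVs, count and curve CSVs."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assays import BindingCurve, MeltCurve
from .enrichment import ClonotypeCountTable
from .library import PeptideCountTable, PositionPreferenceMatrix
from .repertoire import CellRecord, ClonalitySummary, Clonotype

__all__ = [
    "write_fastq_pairs",
    "read_fastq_pairs",
    "write_airr_tsv",
    "write_clonotype_tsv",
    "read_clonotype_tsv",
    "write_clonality_csv",
    "write_count_tables_csv",
    "read_count_tables_csv",
    "write_preference_csv",
    "read_curve_csv",
    "read_clonotype_counts_csv",
    "write_enriched_csv",
]


def write_fastq_pairs(pairs: Iterable, r1_path: str | Path, r2_path: str | Path) -> None:
    """Write (id, r1, q1, r2, q2) tuples as paired Phred+33 FASTQ files."""
    recs1, recs2 = [], []
    for rid, r1, q1, r2, q2 in pairs:
        rec1 = SeqRecord(Seq(r1), id=rid, description="")
        rec1.letter_annotations["phred_quality"] = [ord(c) - 33 for c in q1]
        rec2 = SeqRecord(Seq(r2), id=rid, description="")
        rec2.letter_annotations["phred_quality"] = [ord(c) - 33 for c in q2]
        recs1.append(rec1)
        recs2.append(rec2)
    SeqIO.write(recs1, str(r1_path), "fastq")
    SeqIO.write(recs2, str(r2_path), "fastq")


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[tuple]:
    """Read paired FASTQ files into (id, r1, q1, r2, q2) tuples."""
    out = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(r1_path), "fastq"), SeqIO.parse(str(r2_path), "fastq")
    ):
        if rec1.id != rec2.id:
            raise ValueError(f"read id mismatch: {rec1.id} vs {rec2.id}")
        q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
        out.append((rec1.id, str(rec1.seq), q1, str(rec2.seq), q2))
    return out


def write_airr_tsv(cells: Sequence[CellRecord], path: str | Path) -> None:
    """Write per-chain rearrangement rows (AIRR-C style columns)."""
    rows = []
    for cell in cells:
        cell_id = "_".join(str(x) for x in cell.well_id)
        for chain, locus in (("alpha", "TRA"), ("beta", "TRB")):
            ann = getattr(cell, chain)
            if ann is None:
                continue
            rows.append(
                {
                    "cell_id": cell_id,
                    "locus": locus,
                    "v_call": ann.v_call,
                    "d_call": ann.d_call or "",
                    "j_call": ann.j_call,
                    "junction": ann.cdr3_nt or "",
                    "junction_aa": ann.cdr3_aa or "",
                    "productive": "T" if ann.productive else "F",
                    "consensus_count": ann.consensus_count,
                    "status": cell.status,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_CLONOTYPE_COLS = [
    "id", "size", "sample", "cdr3_alpha_aa", "v_alpha", "j_alpha",
    "cdr3_beta_aa", "v_beta", "d_beta", "j_beta",
    "cdr3_alpha_nt", "cdr3_beta_nt",
]


def write_clonotype_tsv(clonotypes: Sequence[Clonotype], path: str | Path) -> None:
    rows = [
        {col: getattr(c, col if col != "size" else "size") for col in _CLONOTYPE_COLS}
        for c in clonotypes
    ]
    pd.DataFrame(rows, columns=_CLONOTYPE_COLS).to_csv(path, sep="\t", index=False)


def read_clonotype_tsv(path: str | Path) -> list[Clonotype]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str}, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            Clonotype(
                id=str(r["id"]),
                cdr3_alpha_aa=str(r["cdr3_alpha_aa"]),
                cdr3_beta_aa=str(r["cdr3_beta_aa"]),
                v_alpha=str(r["v_alpha"]),
                j_alpha=str(r["j_alpha"]),
                v_beta=str(r["v_beta"]),
                j_beta=str(r["j_beta"]),
                d_beta=str(r["d_beta"]) or None,
                size=int(r["size"]),
                sample=str(r["sample"]),
                member_wells=[],
                cdr3_alpha_nt=str(r["cdr3_alpha_nt"]),
                cdr3_beta_nt=str(r["cdr3_beta_nt"]),
            )
        )
    return out


def write_clonality_csv(summary: ClonalitySummary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["clonotype_id", "fraction"])
        for cid, frac in sorted(summary.fractions.items(), key=lambda kv: (-kv[1], kv[0])):
            w.writerow([cid, f"{frac:.6g}"])
        w.writerow([f"top_{summary.top_k}_cumulative", f"{summary.top_k_cumulative_fraction:.6g}"])
        w.writerow(["total_cells", summary.total_cells])


def write_count_tables_csv(tables: Sequence[PeptideCountTable], path: str | Path) -> None:
    """Per-round peptide counts as CSV (columns: round, peptide, count)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["round", "peptide", "count"])
        for t in tables:
            for pep in sorted(t.counts):
                w.writerow([t.round_index, pep, t.counts[pep]])


def read_count_tables_csv(path: str | Path, tcr_label: str = "") -> list[PeptideCountTable]:
    df = pd.read_csv(path)
    tables = []
    for rnd, grp in df.groupby("round", sort=True):
        tables.append(
            PeptideCountTable(
                round_index=int(rnd),
                counts=dict(zip(grp["peptide"], grp["count"].astype(int))),
                tcr_label=tcr_label,
            )
        )
    return tables


def write_preference_csv(matrix: PositionPreferenceMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index_label="position")


def read_curve_csv(path: str | Path, kind: str = "binding"):
    """Read an x,y curve CSV as a BindingCurve or MeltCurve."""
    df = pd.read_csv(path)
    x, y = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    if kind == "binding":
        return BindingCurve(concentrations=x, responses=y)
    if kind == "melt":
        return MeltCurve(temperatures=x, fluorescence=y)
    raise ValueError(f"unknown curve kind {kind!r}")


def read_clonotype_counts_csv(path: str | Path) -> ClonotypeCountTable:
    """CSV with columns clonotype_id,n_pos,n_neg (optional totals row '_total')."""
    df = pd.read_csv(path, dtype={0: str})
    totals = None
    rows = {}
    for _, r in df.iterrows():
        cid = str(r.iloc[0])
        if cid == "_total":
            totals = (int(r.iloc[1]), int(r.iloc[2]))
        else:
            rows[cid] = (int(r.iloc[1]), int(r.iloc[2]))
    return ClonotypeCountTable(rows=rows, totals=totals)


def write_enriched_csv(enriched, path: str | Path) -> None:
    rows = [
        {
            "clonotype_id": e.clonotype_id,
            "n_pos": e.n_pos,
            "n_neg": e.n_neg,
            "freq_pos": e.freq_pos,
            "freq_neg_adjusted": e.freq_neg_adjusted,
            "fold": e.fold,
            "fold_unadjusted": e.fold_unadjusted,
        }
        for e in enriched
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
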