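"""Packaged reference datasets.

``p15e_public_clones``: the panel of highly homologous p15E-reactive
clonal lineages recovered by plate-based paired TCR sequencing of
activated tumour-infiltrating CD8+ T cells from treated and untreated
B16F10 melanoma mice -- clone name, clone size (member cells), mouse of
origin, paired CDR3s, and V/(D)/J gene usage.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .germline import encode_peptide
from .repertoire import CellRecord, ChainAnnotation, Clonotype, call_clonotypes

__all__ = [
    "load_public_clone_table",
    "public_clone_cells",
    "public_clonotypes",
]


def load_public_clone_table() -> pd.DataFrame:
    """The p15E-reactive public clone panel as a DataFrame."""
    ref = resources.files("mimoseq.data").joinpath("p15e_public_clones.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str).astype({"clone_size": int})


def _annotation(chain: str, cdr3_aa: str, v: str, j: str, d: str | None = None) -> ChainAnnotation:
    return ChainAnnotation(
        chain=chain,
        v_call=v,
        j_call=j,
        d_call=d,
        v_score=float("nan"),
        j_score=float("nan"),
        cdr3_nt=encode_peptide(cdr3_aa),
        cdr3_aa=cdr3_aa,
        productive=True,
    )


def public_clone_cells() -> list[CellRecord]:
    """Expand each panel row into clone-size many identical paired cells."""
    df = load_public_clone_table()
    cells = []
    for _, row in df.iterrows():
        alpha = _annotation(
            "alpha", row.cdr3_alpha, f"TRAV{row.trav}", f"TRAJ{row.traj}"
        )
        beta = _annotation(
            "beta", row.cdr3_beta, f"TRBV{row.trbv}", f"TRBJ{row.trbj}", f"TRBD{row.trbd}"
        )
        for i in range(row.clone_size):
            cells.append(
                CellRecord(
                    well_id=(row.clone_name, i + 1),
                    alpha=alpha,
                    beta=beta,
                    status="paired",
                    sample=row.mouse,
                )
            )
    return cells


def public_clonotypes() -> list[Clonotype]:
    """The panel as called clonal lineages (largest first)."""
    return call_clonotypes(public_clone_cells())
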