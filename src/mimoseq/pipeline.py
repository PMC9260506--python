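"""Pipeline orchestration: configs, manifests, and staged runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from . import io as mio
from .germline import GermlineReference
from .library import (
    design_library,
    enrichment_trajectory,
    extract_region,
    merge_pairs,
    preference_matrix,
    rank_mimotopes,
    tally_peptides,
)
from .motifs import count_motif, gene_usage, group_shared_cdr3
from .repertoire import BarcodeScheme, clonality, default_scheme, process_plate

log = logging.getLogger("mimoseq")

__all__ = ["RunConfig", "run_repertoire", "run_display", "write_manifest"]


@dataclass
class RunConfig:
    """Serializable parameters for a pipeline run (flags override file)."""

    seed: int = 0
    out_dir: str = "mimoseq_out"
    # repertoire stage
    r1: Optional[str] = None
    r2: Optional[str] = None
    germline: Optional[str] = None
    scheme: Optional[str] = None  # JSON barcode scheme; None -> packaged default
    min_overlap: int = 20
    max_mismatch_frac: float = 0.25
    collapse_ratio: float = 5.0
    collapse_max_mm: int = 1
    dominance_threshold: float = 10.0
    clonotype_level: str = "aa"
    top_k: int = 3
    motifs: tuple[str, ...] = ("PPG", "LELGG", "SWT")
    sample: str = ""
    # display stage
    design_template: str = "KSPWFTTL"
    design_positions: tuple[int, ...] = (1, 4, 6, 7)
    codon_scheme: str = "NNK"
    rounds_csv: Optional[str] = None
    trajectory_pseudocount: float = 1.0
    log_level: str = "INFO"

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("motifs", "design_positions"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def parameter_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir: Path, stage: str, outputs: list[str]) -> Path:
    manifest = {
        "tool": "mimoseq",
        "version": __version__,
        "stage": stage,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "parameters": dataclasses.asdict(config),
        "outputs": outputs,
    }
    path = out_dir / f"{stage}_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return path


def _load_scheme(config: RunConfig) -> BarcodeScheme:
    if config.scheme is None:
        return default_scheme()
    with open(config.scheme) as fh:
        data = json.load(fh)
    return BarcodeScheme(
        group_barcodes=data["group_barcodes"],
        plate_barcodes=data["plate_barcodes"],
        column_barcodes=data["column_barcodes"],
        row_barcodes=data["row_barcodes"],
        layout=tuple(data.get("layout", ("group", "plate", "row", "column"))),
        max_mismatch=int(data.get("max_mismatch", 1)),
    )


def run_repertoire(config: RunConfig):
    """FASTQ pairs -> AIRR TSV, clonotype TSV, clonality and motif reports."""
    for name in ("r1", "r2", "germline"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"repertoire stage input '{name}' missing: {path}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = _load_scheme(config)
    reference = GermlineReference.from_fasta(config.germline)
    pairs = mio.read_fastq_pairs(config.r1, config.r2)
    log.info("repertoire: %d read pairs", len(pairs))
    result = process_plate(
        pairs,
        scheme,
        reference,
        min_overlap=config.min_overlap,
        max_mismatch_frac=config.max_mismatch_frac,
        ratio_threshold=config.collapse_ratio,
        max_mm=config.collapse_max_mm,
        dominance_threshold=config.dominance_threshold,
        clonotype_level=config.clonotype_level,
        sample=config.sample,
    )
    outputs = []
    airr = out_dir / "rearrangements.tsv"
    mio.write_airr_tsv(result.cells, airr)
    outputs.append(str(airr))
    ctsv = out_dir / "clonotypes.tsv"
    mio.write_clonotype_tsv(result.clonotypes, ctsv)
    outputs.append(str(ctsv))
    if result.clonotypes:
        summary = clonality(result.clonotypes, k=config.top_k)
        cl = out_dir / "clonality.csv"
        mio.write_clonality_csv(summary, cl)
        outputs.append(str(cl))
        motif_rows = []
        betas = [(c.id, c.cdr3_beta_aa) for c in result.clonotypes]
        for motif in config.motifs:
            mc = count_motif(betas, motif)
            motif_rows.append(
                {"motif": motif, "n_matching": mc.n_matching, "n_total": mc.n_total}
            )
        import pandas as pd

        mpath = out_dir / "motifs.csv"
        pd.DataFrame(motif_rows).to_csv(mpath, index=False)
        outputs.append(str(mpath))
    manifest = write_manifest(config, out_dir, "repertoire", outputs)
    log.info("repertoire: wrote %s", manifest)
    return result


def run_display(config: RunConfig):
    """Per-round counts -> preference matrices and ranked mimotopes."""
    if config.rounds_csv is None or not Path(config.rounds_csv).exists():
        raise FileNotFoundError(f"display stage input 'rounds_csv' missing: {config.rounds_csv}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = design_library(
        config.design_template, set(config.design_positions), config.codon_scheme
    )
    tables = mio.read_count_tables_csv(config.rounds_csv)
    if not tables:
        raise ValueError("no selection rounds in input")
    for t in tables:
        if not t.counts:
            raise ValueError(f"round {t.round_index} has zero accepted reads")
    outputs = []
    for t in tables:
        m = preference_matrix(t, design)
        path = out_dir / f"preference_round{t.round_index}.csv"
        mio.write_preference_csv(m, path)
        outputs.append(str(path))
    trajectories = enrichment_trajectory(tables, pseudocount=config.trajectory_pseudocount)
    ranked = rank_mimotopes(trajectories)
    import pandas as pd

    cand = out_dir / "candidates.csv"
    pd.DataFrame(
        [
            {
                "peptide": c.peptide,
                "final_round_frequency": c.final_round_frequency,
                "cumulative_fold_enrichment": c.cumulative_fold_enrichment,
            }
            for c in ranked
        ]
    ).to_csv(cand, index=False)
    outputs.append(str(cand))
    write_manifest(config, out_dir, "display", outputs)
    return ranked
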