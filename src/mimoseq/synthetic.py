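"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here, with the truth
retained for scoring: plate-barcoded paired alpha/beta amplicon reads with
substitution noise, multinomial round-over-round yeast-display selection
under a planted peptide-binding energy model, tetramer-positive/negative
clonotype capture, and one-site binding / sigmoidal melt curves.  All
generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np

from .assays import BindingCurve, MeltCurve
from .enrichment import ClonotypeCountTable
from .germline import (
    GermlineReference,
    GermlineSegment,
    core_segments,
    translate,
)
from .library import (
    LibraryDesign,
    PeptideCountTable,
    codon_table,
    design_library,
    reverse_complement,
)
from .repertoire import BarcodeScheme, default_scheme

__all__ = [
    "generate_germline_reference",
    "build_chain_nt",
    "PlantedClonotype",
    "PlantedWell",
    "PlantedPlateTruth",
    "plant_plate",
    "ReadPair",
    "SimulatedPlate",
    "simulate_tcr_plate",
    "PositionEnergyModel",
    "PlantedSelectionTruth",
    "default_selection_truth",
    "simulate_selection_campaign",
    "plant_tetramer_scenario",
    "simulate_tetramer_fractions",
    "simulate_binding_curve",
    "simulate_melt_curve",
    "two_fold_series",
]

_BASES = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codon choices per amino acid (standard code), for junction encoding
_AA_TO_CODONS: dict[str, list[str]] = {}
for _c in ("".join(b) for b in itertools.product("ACGT", repeat=3)):
    _AA_TO_CODONS.setdefault(translate(_c), []).append(_c)


# ---------------------------------------------------------------------------
# Germline reference
# ---------------------------------------------------------------------------


def generate_germline_reference(n_per_kind: int = 4, seed: int = 1) -> GermlineReference:
    """Synthetic germline reference with IMGT-like names.

    Always contains the fixed core segments (TRAV10, TRAJ7, TRBV5, ... plus
    TRAC/TRBC) whose junction-proximal residues reconstruct the public
    p15E-reactive CDR3s, extended by ``n_per_kind`` seeded random V and J
    segments per locus.  Deterministic for a fixed seed.
    """
    if n_per_kind < 1:
        raise ValueError("n_per_kind must be >= 1")
    rng = np.random.default_rng(seed)
    segs = core_segments()
    body_alphabet = list(_AA20.replace("C", "").replace("W", ""))

    def random_body(n_aa: int) -> str:
        return "".join(rng.choice(body_alphabet, n_aa))

    def enc(aa: str) -> str:
        return "".join(_AA_TO_CODONS[a][int(rng.integers(len(_AA_TO_CODONS[a])))] for a in aa)

    for i in range(n_per_kind):
        body = random_body(17)
        nt = enc(body) + "TGT" + enc("AA")
        segs.append(GermlineSegment(
            name=f"TRAV{101 + i}", locus="TRA", kind="V", nt=nt,
            conserved_cys_offset=51,
        ))
        body = random_body(16)
        nt = enc(body) + "TGT" + enc("ASS")
        segs.append(GermlineSegment(
            name=f"TRBV{101 + i}", locus="TRB", kind="V", nt=nt,
            conserved_cys_offset=48,
        ))
        cdr3 = random_body(5) + str(rng.choice(["F", "W"]))
        tail = "G" + random_body(1) + "G" + random_body(1)
        nt = enc(cdr3 + tail)
        segs.append(GermlineSegment(
            name=f"TRAJ{40 + i}", locus="TRA", kind="J", nt=nt,
            j_anchor_offset=3 * (len(cdr3) - 1),
        ))
        cdr3 = random_body(5) + str(rng.choice(["F", "W"]))
        nt = enc(cdr3 + "G" + random_body(1) + "G" + random_body(1))
        segs.append(GermlineSegment(
            name=f"TRBJ{40 + i}", locus="TRB", kind="J", nt=nt,
            j_anchor_offset=3 * (len(cdr3) - 1),
        ))
    return GermlineReference(segs)


def build_chain_nt(
    ref: GermlineReference,
    v_name: str,
    j_name: str,
    cdr3_aa: str,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Rearranged chain nucleotide sequence encoding a given CDR3.

    The CDR3 must begin with the V segment's conserved cysteine and end
    with residues templated by the J segment (at least the anchor);
    intervening junction residues get codons drawn from ``rng`` (first
    codon when None), mimicking junctional diversity.
    """
    v = ref.get(v_name)
    j = ref.get(j_name)
    v_tail = v.v_tail_aa
    j_part = j.j_cdr3_aa
    k = 0
    while k < min(len(v_tail), len(cdr3_aa)) and cdr3_aa[k] == v_tail[k]:
        k += 1
    if k == 0:
        raise ValueError(f"CDR3 {cdr3_aa} does not start with {v_name}'s conserved Cys")
    m = 0
    while (
        m < len(j_part)
        and k + m < len(cdr3_aa)
        and cdr3_aa[len(cdr3_aa) - 1 - m] == j_part[len(j_part) - 1 - m]
    ):
        m += 1
    if m == 0:
        raise ValueError(f"CDR3 {cdr3_aa} does not end with {j_name}'s anchor residue")
    mid = cdr3_aa[k: len(cdr3_aa) - m]
    if rng is None:
        mid_nt = "".join(_AA_TO_CODONS[a][0] for a in mid)
    else:
        mid_nt = "".join(
            _AA_TO_CODONS[a][int(rng.integers(len(_AA_TO_CODONS[a])))] for a in mid
        )
    return (
        v.nt[: v.conserved_cys_offset + 3 * k]
        + mid_nt
        + j.nt[3 * (len(j_part) - m):]
    )


# ---------------------------------------------------------------------------
# Plate simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedClonotype:
    id: str
    cdr3_alpha_aa: str
    cdr3_beta_aa: str
    v_alpha: str
    j_alpha: str
    v_beta: str
    j_beta: str
    alpha_nt: str  # full chain amplicon incl. constant fragment
    beta_nt: str


class PlantedWell(NamedTuple):
    alpha_nt: str
    beta_nt: str
    clonotype_id: str


@dataclass
class PlantedPlateTruth:
    """Planted single-cell plate: one clonotype's chains per well."""

    wells: dict[tuple, PlantedWell]
    clonotypes: dict[str, PlantedClonotype]
    error_rate: float = 0.01
    depth: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def plant_plate(
    reference: GermlineReference,
    scheme: Optional[BarcodeScheme] = None,
    n_wells: int = 96,
    n_clonotypes: int = 12,
    depth: int = 50,
    error_rate: float = 0.01,
    seed: int = 0,
) -> PlantedPlateTruth:
    """Plant an oligoclonal sorted plate: wells drawn from a clone pool.

    Clone frequencies follow a 1/rank power law, emulating the oligoclonal
    expansions seen in sorted activated tumour-infiltrating T cells.
    """
    if scheme is None:
        scheme = default_scheme()
    rng = np.random.default_rng(seed)
    tra_v = reference.by_kind("TRA", "V")
    tra_j = reference.by_kind("TRA", "J")
    trb_v = reference.by_kind("TRB", "V")
    trb_j = reference.by_kind("TRB", "J")
    const = reference.constant_refs()
    clonotypes: dict[str, PlantedClonotype] = {}
    for i in range(n_clonotypes):
        va = tra_v[int(rng.integers(len(tra_v)))]
        ja = tra_j[int(rng.integers(len(tra_j)))]
        vb = trb_v[int(rng.integers(len(trb_v)))]
        jb = trb_j[int(rng.integers(len(trb_j)))]
        mid_a = "".join(rng.choice(list(_AA20), int(rng.integers(1, 4))))
        mid_b = "".join(rng.choice(list(_AA20), int(rng.integers(2, 6))))
        cdr3a = va.v_tail_aa + mid_a + ja.j_cdr3_aa
        cdr3b = vb.v_tail_aa + mid_b + jb.j_cdr3_aa
        cid = f"planted_{i + 1:03d}"
        clonotypes[cid] = PlantedClonotype(
            id=cid,
            cdr3_alpha_aa=cdr3a,
            cdr3_beta_aa=cdr3b,
            v_alpha=va.name,
            j_alpha=ja.name,
            v_beta=vb.name,
            j_beta=jb.name,
            alpha_nt=build_chain_nt(reference, va.name, ja.name, cdr3a, rng) + const["alpha"],
            beta_nt=build_chain_nt(reference, vb.name, jb.name, cdr3b, rng) + const["beta"],
        )
    ids = sorted(clonotypes)
    weights = 1.0 / np.arange(1, len(ids) + 1)
    weights /= weights.sum()
    well_ids = list(itertools.product(
        sorted(scheme.group_barcodes),
        sorted(scheme.plate_barcodes),
        sorted(scheme.row_barcodes),
        sorted(scheme.column_barcodes, key=lambda x: int(x) if x.isdigit() else x),
    ))[:n_wells]
    if len(well_ids) < n_wells:
        raise ValueError("barcode scheme addresses fewer wells than requested")
    wells = {}
    for w in well_ids:
        cid = ids[int(rng.choice(len(ids), p=weights))]
        ct = clonotypes[cid]
        wells[w] = PlantedWell(ct.alpha_nt, ct.beta_nt, cid)
    return PlantedPlateTruth(
        wells=wells, clonotypes=clonotypes,
        error_rate=error_rate, depth=depth, seed=seed,
    )


class ReadPair(NamedTuple):
    id: str
    r1: str
    q1: str
    r2: str
    q2: str


@dataclass
class SimulatedPlate:
    read_pairs: list[ReadPair]
    read_truth: dict[str, tuple[tuple, str]]  # read id -> (well_id, chain)
    truth: PlantedPlateTruth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    base_codes = np.frombuffer(b"ACGT", np.uint8)
    for i in hits:
        choices = base_codes[base_codes != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_tcr_plate(
    truth: PlantedPlateTruth,
    scheme: Optional[BarcodeScheme] = None,
    read_length: int = 120,
    quality_char: str = "?",  # Q30
    seed: Optional[int] = None,
) -> SimulatedPlate:
    """Paired-end amplicon reads for a planted plate.

    Each fragment is the four well barcodes (group/plate/row/column order
    per the scheme layout) followed by the chain amplicon; read 1 covers
    the 5' end, read 2 the reverse complement of the 3' end, with
    independent i.i.d. substitution errors at ``truth.error_rate``.
    """
    if scheme is None:
        scheme = default_scheme()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    fields = {name: scheme.field(name) for name in ("group", "plate", "row", "column")}
    pairs: list[ReadPair] = []
    read_truth: dict[str, tuple[tuple, str]] = {}
    counter = 0
    for well in sorted(truth.wells):
        labels = dict(zip(("group", "plate", "row", "column"), well))
        prefix = "".join(fields[name][labels[name]] for name in scheme.layout)
        planted = truth.wells[well]
        for chain, chain_nt in (("alpha", planted.alpha_nt), ("beta", planted.beta_nt)):
            frag = prefix + chain_nt
            rc = reverse_complement(frag)
            for _ in range(truth.depth):
                r1 = _mutate(frag[:read_length], truth.error_rate, rng)
                r2 = _mutate(rc[:read_length], truth.error_rate, rng)
                rid = f"sim{counter:07d}"
                counter += 1
                pairs.append(ReadPair(rid, r1, quality_char * len(r1), r2, quality_char * len(r2)))
                read_truth[rid] = (well, chain)
    return SimulatedPlate(read_pairs=pairs, read_truth=read_truth, truth=truth)


# ---------------------------------------------------------------------------
# Selection campaign
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PositionEnergyModel:
    """Additive per-position binding energies (lower = tighter binding)."""

    position_energies: Mapping[int, Mapping[str, float]]
    default: float = 3.0

    def __call__(self, peptide: str) -> float:
        e = 0.0
        for pos, table in self.position_energies.items():
            e += table.get(peptide[pos - 1], self.default)
        return e

    @property
    def minimum_energy_peptide_choices(self) -> dict[int, str]:
        out = {}
        for pos, table in self.position_energies.items():
            out[pos] = min(sorted(table), key=lambda a: table[a])
        return out


EnergyFunction = Union[Mapping[str, float], Callable[[str], float]]


@dataclass
class PlantedSelectionTruth:
    """Planted yeast-display selection campaign."""

    design: LibraryDesign
    energies: EnergyFunction
    stringency: float = 1.0
    depth_per_round: int = 100_000
    n_rounds: int = 3
    seed: int = 0
    tcr_label: str = ""
    initial_counts: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        if self.depth_per_round <= 0:
            raise ValueError("depth_per_round must be > 0")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")

    def energy(self, peptide: str) -> float:
        if callable(self.energies):
            return float(self.energies(peptide))
        return float(self.energies[peptide])

    @property
    def planted_binder(self) -> str:
        """Lowest-energy peptide under an additive energy model."""
        if isinstance(self.energies, PositionEnergyModel):
            best = self.energies.minimum_energy_peptide_choices
            return "".join(
                best.get(i + 1, a) for i, a in enumerate(self.design.template_peptide)
            )
        if isinstance(self.energies, Mapping):
            return min(sorted(self.energies), key=lambda p: self.energies[p])
        raise ValueError("planted binder undefined for an opaque energy callable")


#: Planted energies for the p15E XSPXFXXL campaign: the wild-type-like
#: residue costs 0, a tolerated substitution ~1, everything else 3; the
#: unique minimum-energy peptide is the mimotope-like KSPWFITL.
DEFAULT_ENERGY_MODEL = PositionEnergyModel(
    position_energies={
        1: {"K": 0.0, "V": 0.5},
        4: {"W": 0.0, "Y": 1.0},
        6: {"I": 0.0, "T": 1.2, "N": 1.5},
        7: {"T": 0.0, "N": 0.4},
    },
    default=3.0,
)


def default_selection_truth(
    seed: int = 0,
    stringency: float = 1.0,
    depth_per_round: int = 100_000,
    n_rounds: int = 3,
    tcr_label: str = "7PPG4",
) -> PlantedSelectionTruth:
    """The default p15E mimotope campaign: XSPXFXXL with NNK codons."""
    design = design_library("KSPWFTTL", {1, 4, 6, 7}, "NNK")
    return PlantedSelectionTruth(
        design=design,
        energies=DEFAULT_ENERGY_MODEL,
        stringency=stringency,
        depth_per_round=depth_per_round,
        n_rounds=n_rounds,
        seed=seed,
        tcr_label=tcr_label,
    )


def simulate_selection_campaign(truth: PlantedSelectionTruth) -> list[PeptideCountTable]:
    """Multinomial round-over-round selection under the planted energies.

    Round 0 is the naive library: the design's codon space enumerated
    uniformly (every nucleotide variant once, emulating a transformant
    library at full coverage), translated, stop-containing variants
    filtered -- so each peptide's round-0 count is its codon multiplicity.
    Round t+1 counts are multinomial draws of ``depth_per_round`` with
    weights proportional to count_t(p) * exp(-stringency * energy(p)).
    Returns one count table per round (round 0 included).
    """
    rng = np.random.default_rng(truth.seed)
    design = truth.design
    positions = sorted(design.diversified_positions)
    if truth.initial_counts is not None:
        counts = {p: int(c) for p, c in truth.initial_counts.items() if c > 0}
    else:
        table = codon_table(design.codon_scheme)
        mult: dict[str, int] = {}
        for aa in table.values():
            if aa != "*":
                mult[aa] = mult.get(aa, 0) + 1
        aa_list = sorted(mult)
        counts = {}
        template = design.template_peptide
        for combo in itertools.product(aa_list, repeat=len(positions)):
            residues = list(template)
            m = 1
            for pos, a in zip(positions, combo):
                residues[pos - 1] = a
                m *= mult[a]
            counts["".join(residues)] = m
    tables = [PeptideCountTable(round_index=0, counts=dict(counts), tcr_label=truth.tcr_label)]
    for t in range(1, truth.n_rounds + 1):
        peps = sorted(counts)
        c = np.array([counts[p] for p in peps], dtype=float)
        e = np.array([truth.energy(p) for p in peps])
        w = c * np.exp(-truth.stringency * e)
        probs = w / w.sum()
        drawn = rng.multinomial(truth.depth_per_round, probs)
        counts = {p: int(n) for p, n in zip(peps, drawn) if n > 0}
        tables.append(PeptideCountTable(round_index=t, counts=counts, tcr_label=truth.tcr_label))
    return tables


# ---------------------------------------------------------------------------
# Tetramer fractions
# ---------------------------------------------------------------------------


def plant_tetramer_scenario(
    n_specific: int = 20,
    n_background: int = 180,
    specific_mass: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, float], set[str]]:
    """Planted repertoire for a tetramer sort.

    Specific clonotypes are clonally expanded (geometrically decaying
    frequencies summing to ``specific_mass``); the background is a flat
    Dirichlet repertoire carrying the remaining mass.
    """
    rng = np.random.default_rng(seed)
    spec_w = 0.85 ** np.arange(n_specific)
    spec_w = spec_w / spec_w.sum() * specific_mass
    bg_w = rng.dirichlet(np.ones(n_background)) * (1.0 - specific_mass)
    freqs = {f"S{i + 1:03d}": float(w) for i, w in enumerate(spec_w)}
    freqs.update({f"B{i + 1:03d}": float(w) for i, w in enumerate(bg_w)})
    return freqs, {f"S{i + 1:03d}" for i in range(n_specific)}


def simulate_tetramer_fractions(
    freqs: Mapping[str, float],
    specific: set[str],
    capture_p: float = 0.9,
    leak_p: float = 0.01,
    n_pos: int = 2000,
    n_neg: int = 2000,
    seed: int = 0,
) -> ClonotypeCountTable:
    """Sample tetramer-positive and -negative sorted fractions.

    The positive fraction samples clonotypes with weight freq*capture_p
    (specific) or freq*leak_p (non-specific); the negative fraction uses
    the complementary weights.  Totals equal ``n_pos`` and ``n_neg``.
    """
    if not freqs:
        raise ValueError("empty clonotype frequencies")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    if not 0 <= leak_p < capture_p <= 1:
        raise ValueError("need 0 <= leak_p < capture_p <= 1")
    rng = np.random.default_rng(seed)
    ids = sorted(freqs)
    f = np.array([freqs[i] for i in ids])
    is_spec = np.array([i in specific for i in ids])
    pos_w = f * np.where(is_spec, capture_p, leak_p)
    neg_w = f * np.where(is_spec, 1.0 - capture_p, 1.0 - leak_p)
    rows: dict[str, tuple[int, int]] = {}
    pos_counts = (
        rng.multinomial(n_pos, pos_w / pos_w.sum()) if pos_w.sum() > 0 else np.zeros(len(ids), int)
    )
    neg_counts = (
        rng.multinomial(n_neg, neg_w / neg_w.sum()) if neg_w.sum() > 0 else np.zeros(len(ids), int)
    )
    for i, cid in enumerate(ids):
        if pos_counts[i] or neg_counts[i]:
            rows[cid] = (int(pos_counts[i]), int(neg_counts[i]))
    return ClonotypeCountTable(rows=rows, totals=(n_pos, n_neg))


# ---------------------------------------------------------------------------
# Assay curves
# ---------------------------------------------------------------------------


def two_fold_series(low: float = 0.35, high: float = 266.0) -> list[float]:
    """Two-fold dilution series spanning [low, high] (top dose included)."""
    concs = []
    c = low
    while c <= high:
        concs.append(round(c, 6))
        c *= 2.0
    if concs[-1] < high:
        concs.append(high)
    return concs


def simulate_binding_curve(
    kd: float,
    rmax: float,
    concs: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BindingCurve:
    """Steady-state one-site binding responses with Gaussian noise."""
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be positive")
    c = np.asarray(concs, dtype=float)
    if c.size == 0 or np.any(c <= 0):
        raise ValueError("concentrations must be non-empty and positive")
    rng = np.random.default_rng(seed)
    r = rmax * c / (kd + c)
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, size=c.shape)
    return BindingCurve(concentrations=c, responses=r)


def simulate_melt_curve(
    tm: float,
    width: float,
    f_low: float,
    f_high: float,
    temps: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MeltCurve:
    """Sigmoidal unfolding trace F = f_low + (f_high-f_low)/(1+exp((tm-T)/width))."""
    if width <= 0:
        raise ValueError("width must be positive")
    t = np.asarray(temps, dtype=float)
    rng = np.random.default_rng(seed)
    f = f_low + (f_high - f_low) / (1.0 + np.exp((tm - t) / width))
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=t.shape)
    return MeltCurve(temperatures=t, fluorescence=f)
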