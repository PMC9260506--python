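"""Demultiplexing, collapse, annotation, pairing and clonotype calling."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimoseq.germline import GermlineReference, GermlineSegment, encode_peptide
from mimoseq.repertoire import (
    BarcodeCollisionError,
    BarcodeScheme,
    Read,
    UnannotatableError,
    annotate_vj,
    assign_chain,
    call_clonotypes,
    clonality,
    collapse_reads,
    default_scheme,
    demultiplex,
    extract_cdr3,
    flag_contaminants,
    pair_well,
    process_plate,
)
from mimoseq.synthetic import (
    build_chain_nt,
    plant_plate,
    simulate_tcr_plate,
)


def tiny_scheme(max_mismatch=1):
    return BarcodeScheme(
        group_barcodes={"g1": "AAAA", "g2": "TTTT"},
        plate_barcodes={"p1": "CCCC", "p2": "GGGG"},
        row_barcodes={"rA": "AACC", "rB": "TTGG"},
        column_barcodes={"c3": "ACAC", "c4": "GTGT"},
        max_mismatch=max_mismatch,
    )


class TestDemultiplex:
    def test_exact_barcodes_assign(self):
        s = tiny_scheme()
        read = Read("r1", "AAAA" + "CCCC" + "AACC" + "ACAC" + "ACGTACGT")
        assigned, unassigned = demultiplex([read], s)
        assert list(assigned) == [("g1", "p1", "rA", "c3")]
        assert not unassigned

    def test_single_mismatch_within_tolerance_assigns(self):
        s = tiny_scheme(max_mismatch=1)
        read = Read("r1", "AAAT" + "CCCC" + "AACC" + "ACAC")
        assigned, _ = demultiplex([read], s)
        assert ("g1", "p1", "rA", "c3") in assigned

    def test_equidistant_barcodes_are_ambiguous(self):
        s = BarcodeScheme(
            group_barcodes={"g1": "AAAA"},
            plate_barcodes={"p1": "CCCC"},
            row_barcodes={"rA": "AAAA", "rB": "AATT"},  # distance 2
            column_barcodes={"c1": "ACAC"},
        )
        # row segment AATA is at distance 1 from both row barcodes
        read = Read("r1", "AAAA" + "CCCC" + "AATA" + "ACAC")
        assigned, unassigned = demultiplex([read], s)
        assert not assigned
        assert unassigned[0][1] == "ambiguous"

    def test_short_read_unassigned_with_reason(self):
        assigned, unassigned = demultiplex([Read("r1", "AAA")], tiny_scheme())
        assert unassigned[0][1] == "too_short"

    def test_partition_property(self, reference, scheme):
        truth = plant_plate(reference, scheme, n_wells=8, depth=5, seed=7)
        sim = simulate_tcr_plate(truth, scheme)
        reads = [Read(rp.id, rp.r1, rp.q1) for rp in sim.read_pairs]
        assigned, unassigned = demultiplex(reads, scheme)
        n_assigned = sum(len(v) for v in assigned.values())
        assert n_assigned + len(unassigned) == len(reads)
        seen = [r.id for rs in assigned.values() for r in rs]
        assert len(seen) == len(set(seen))

    def test_barcode_collision_is_configuration_error(self):
        with pytest.raises(BarcodeCollisionError):
            BarcodeScheme(
                group_barcodes={"g1": "AAAA", "g2": "AAAT"},  # distance 1
                plate_barcodes={"p1": "CCCC"},
                row_barcodes={"rA": "AACC"},
                column_barcodes={"c1": "ACAC"},
            )


class TestAssignChain:
    def test_exact_constant_fragment(self, reference):
        const = reference.constant_refs()
        assert assign_chain("ACGT" * 5 + const["alpha"], const) == "alpha"
        assert assign_chain("ACGT" * 5 + const["beta"], const) == "beta"

    def test_no_constant_match_is_unknown(self, reference):
        assert assign_chain("ACGT" * 30, reference.constant_refs()) == "unknown"

    def test_high_accuracy_on_noisy_plate(self, reference, scheme):
        truth = plant_plate(reference, scheme, n_wells=24, depth=20,
                            error_rate=0.01, seed=13)
        sim = simulate_tcr_plate(truth, scheme)
        const = reference.constant_refs()
        prefix = scheme.prefix_length
        correct = total = 0
        for rp in sim.read_pairs:
            _, chain = sim.read_truth[rp.id]
            # read 2 covers the constant-bearing 3' end
            from mimoseq.library import reverse_complement

            called = assign_chain(reverse_complement(rp.r2), const)
            if called != "unknown":
                total += 1
                correct += called == chain
        assert total / len(sim.read_pairs) > 0.98
        assert correct / total >= 0.995


def brute_force_collapse(counts: dict[str, int], ratio: float, max_mm: int):
    """Independent statement of the absorption rule by direct evaluation."""

    def ham(a, b):
        return sum(x != y for x, y in zip(a, b)) if len(a) == len(b) else max_mm + 1

    def absorber(s):
        cands = [
            t for t in counts
            if counts[t] > counts[s] and counts[t] >= ratio * counts[s]
            and ham(s, t) <= max_mm
        ]
        if not cands:
            return None
        best = sorted(cands, key=lambda t: (-counts[t], t))[0]
        nxt = absorber(best)
        return nxt if nxt is not None else best

    support = Counter()
    for s, c in counts.items():
        target = absorber(s)
        support[target if target is not None else s] += c
    return sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))


class TestCollapseReads:
    def test_dominant_absorbs_singleton_variants(self):
        reads = ["ACGTACGT"] * 100 + ["ACGTACGA", "ACGAACGT", "TCGTACGT"]
        assert collapse_reads(reads, ratio_threshold=10, max_mm=1) == [("ACGTACGT", 103)]

    def test_balanced_variants_both_retained(self):
        reads = ["AAAA"] * 50 + ["AAAT"] * 50
        out = collapse_reads(reads, ratio_threshold=10, max_mm=1)
        assert sorted(out) == [("AAAA", 50), ("AAAT", 50)]

    def test_single_read_is_its_own_consensus(self):
        assert collapse_reads(["ACGT"]) == [("ACGT", 1)]

    def test_empty_input(self):
        assert collapse_reads([]) == []

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        st.dictionaries(
            st.text(alphabet="AC", min_size=4, max_size=4),
            st.integers(min_value=1, max_value=40),
            min_size=1,
            max_size=6,
        ),
        st.sampled_from([2.0, 5.0, 10.0]),
    )
    def test_matches_brute_force_on_small_inputs(self, counts, ratio):
        reads = [s for s, c in counts.items() for _ in range(c)]
        assert collapse_reads(reads, ratio_threshold=ratio, max_mm=1) == \
            brute_force_collapse(counts, ratio, 1)


class TestAnnotateVJ:
    def test_planted_v_j_calls_recovered(self, reference):
        nt = build_chain_nt(reference, "TRAV10", "TRAJ7", "CAAKDYSNNRLTL")
        ann = annotate_vj(nt, reference, "alpha")
        assert (ann.v_call, ann.j_call) == ("TRAV10", "TRAJ7")
        assert ann.cdr3_aa == "CAAKDYSNNRLTL"
        assert ann.productive

    def test_score_tie_broken_lexicographically(self, reference):
        v = reference.get("TRAV10")
        dup = GermlineReference([
            GermlineSegment("TRAV900", "TRA", "V", v.nt, v.conserved_cys_offset),
            GermlineSegment("TRAV901", "TRA", "V", v.nt, v.conserved_cys_offset),
            reference.get("TRAJ7"),
        ])
        nt = build_chain_nt(reference, "TRAV10", "TRAJ7", "CAAKDYSNNRLTL")
        ann = annotate_vj(nt, dup, "alpha")
        assert ann.v_call == "TRAV900"

    def test_random_sequence_unannotatable(self, reference):
        import numpy as np

        rng = np.random.default_rng(99)
        nt = "".join(rng.choice(list("ACGT"), 60))
        with pytest.raises(UnannotatableError) as err:
            annotate_vj(nt, reference, "alpha")
        assert err.value.v_best is not None


class TestExtractCdr3:
    def test_public_alpha_junction(self, reference):
        nt = build_chain_nt(reference, "TRAV7-2", "TRAJ7", "CAAKDYSNNRLTL")
        ann = annotate_vj(nt, reference, "alpha")
        assert ann.cdr3_aa == "CAAKDYSNNRLTL"

    def test_public_beta_junction(self, reference):
        nt = build_chain_nt(reference, "TRBV3", "TRBJ2-5", "CASSPPGDTQYF")
        ann = annotate_vj(nt, reference, "beta")
        assert ann.cdr3_aa == "CASSPPGDTQYF"

    def test_internal_stop_is_nonproductive(self):
        nt = "TGT" + "TAA" + "TTT"
        cdr3_nt, cdr3_aa, productive = extract_cdr3(nt, 0, 6)
        assert cdr3_aa == "C*F"
        assert not productive

    def test_frame_break_is_nonproductive(self):
        _, _, productive = extract_cdr3("TGTAATTT", 0, 5)
        assert not productive


class TestPairWell:
    @staticmethod
    def fake_annotate(nt, chain):
        from mimoseq.repertoire import ChainAnnotation

        return ChainAnnotation(chain, "V", "J", None, 1.0, 1.0, nt, None, True, nt=nt)

    def test_one_alpha_one_beta_pairs(self):
        cell = pair_well(("w",), {"alpha": [("AAA", 5)], "beta": [("CCC", 4)]},
                         self.fake_annotate)
        assert cell.status == "paired"

    def test_dominant_alpha_rescued(self):
        cell = pair_well(("w",), {"alpha": [("AAA", 90), ("AAT", 5)],
                                  "beta": [("CCC", 4)]},
                         self.fake_annotate, dominance_threshold=10)
        assert cell.status == "paired"
        assert cell.alpha.nt == "AAA"

    def test_balanced_duplicates_are_multiplet(self):
        cell = pair_well(("w",), {"alpha": [("AAA", 50), ("AAT", 50)],
                                  "beta": [("CCC", 4)]},
                         self.fake_annotate)
        assert cell.status == "multiplet"

    def test_missing_chain_statuses(self):
        assert pair_well(("w",), {"alpha": [("AAA", 5)]}, self.fake_annotate).status == "alpha_only"
        assert pair_well(("w",), {"beta": [("AAA", 5)]}, self.fake_annotate).status == "beta_only"
        assert pair_well(("w",), {}, self.fake_annotate).status == "empty"


class TestCallClonotypes:
    def test_public_panel_round_trip(self, public_lineages, clone_table):
        assert len(public_lineages) == len(clone_table)
        assert public_lineages[0].size == clone_table.clone_size.max() == 26
        assert sorted(c.size for c in public_lineages) == sorted(clone_table.clone_size)

    def test_order_invariance(self):
        from mimoseq.datasets import public_clone_cells

        cells = public_clone_cells()
        forward = call_clonotypes(cells)
        backward = call_clonotypes(list(reversed(cells)))
        assert [(c.cdr3_beta_aa, c.size) for c in forward] == \
            [(c.cdr3_beta_aa, c.size) for c in backward]

    def test_v_gene_is_part_of_lineage_key(self):
        from mimoseq.repertoire import CellRecord, ChainAnnotation

        def cell(vb):
            a = ChainAnnotation("alpha", "TRAV1", "TRAJ1", None, 1, 1, "TGT", "C", True)
            b = ChainAnnotation("beta", vb, "TRBJ1", None, 1, 1, "TGT", "C", True)
            return CellRecord(("w", vb), a, b, "paired")

        assert len(call_clonotypes([cell("TRBV1"), cell("TRBV2")])) == 2

    def test_size_conservation(self, public_lineages):
        assert sum(c.size for c in public_lineages) == 90


class TestContaminationAndClonality:
    def test_exact_nt_match_flags(self, public_lineages):
        bad = public_lineages[0].cdr3_alpha_nt
        flags = flag_contaminants(public_lineages, blacklist_nt={bad})
        assert flags[public_lineages[0].id]

    def test_near_match_not_flagged(self, public_lineages):
        bad = "A" + public_lineages[0].cdr3_alpha_nt[1:]
        flags = flag_contaminants(public_lineages, blacklist_nt={bad})
        assert not flags[public_lineages[0].id]

    def test_clonality_arithmetic(self):
        from mimoseq.repertoire import Clonotype

        def clone(i, size):
            return Clonotype(f"c{i}", "C", "C", "V", "J", "V", "J", None,
                             size, "", [])

        clones = [clone(i, s) for i, s in enumerate([4, 3, 2, 1])]
        summary = clonality(clones, k=3)
        assert summary.top_k_cumulative_fraction == pytest.approx(0.9)
        assert sum(summary.fractions.values()) == pytest.approx(1.0)
        summary_all = clonality(clones[:3], k=3)
        assert summary_all.top_k_cumulative_fraction == pytest.approx(1.0)

    def test_empty_clonality_rejected(self):
        with pytest.raises(ValueError):
            clonality([], k=1)


class TestEndToEnd:
    def test_single_plate_recovery(self, reference, scheme):
        truth = plant_plate(reference, scheme, n_wells=24, n_clonotypes=6,
                            depth=50, error_rate=0.01, seed=21)
        sim = simulate_tcr_plate(truth, scheme)
        result = process_plate(sim.read_pairs, scheme, reference)
        ok = 0
        for cell in result.cells:
            ct = truth.clonotypes[truth.wells[cell.well_id].clonotype_id]
            ok += (
                cell.status == "paired"
                and cell.alpha.cdr3_aa == ct.cdr3_alpha_aa
                and cell.beta.cdr3_aa == ct.cdr3_beta_aa
                and cell.alpha.v_call == ct.v_alpha
                and cell.beta.v_call == ct.v_beta
            )
        assert ok / len(truth.wells) >= 0.9
        assert sum(c.size for c in result.clonotypes) == \
            sum(1 for c in result.cells if c.status == "paired")
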