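"""Library design, read merging, translate filter, preferences, trajectories."""

import itertools
import math

import numpy as np
import pytest

from mimoseq.germline import translate
from mimoseq.library import (
    AA_ORDER,
    PeptideCountTable,
    codon_table,
    design_library,
    diversity,
    enrichment_trajectory,
    extract_region,
    merge_pairs,
    pooled_counts,
    preference_matrix,
    rank_mimotopes,
    reverse_complement,
    tally_peptides,
    translate_filter,
)
from mimoseq.synthetic import (
    PlantedSelectionTruth,
    default_selection_truth,
    simulate_selection_campaign,
)


class TestDesign:
    def test_p15e_template_string(self):
        design = design_library("KSPWFTTL", {1, 4, 6, 7}, "NNK")
        assert design.template_string == "XSPXFXXL"
        assert design.oligo.count("NNK") == 4
        assert len(design.oligo) == 24

    def test_no_diversified_positions(self):
        design = design_library("KSPWFTTL", set(), "NNK")
        assert design.template_string == "KSPWFTTL"
        assert "N" not in design.oligo and "K" not in design.oligo.replace("AAG", "")

    def test_arbitrary_template(self):
        assert design_library("SIINFEKL", {2, 3}, "NNK").template_string == "SXXNFEKL"

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            design_library("KSPWFTTL", {9})


class TestCodonTable:
    def test_nnk_enumeration(self):
        table = codon_table("NNK")
        assert len(table) == 32
        assert set(table.values()) - {"*"} == set(AA_ORDER)
        assert {c for c, aa in table.items() if aa == "*"} == {"TAG"}

    def test_nnk_agrees_with_brute_force_genetic_code(self):
        brute = {
            c: translate(c)
            for c in ("".join(b) for b in itertools.product("ACGT", repeat=3))
            if c[2] in "GT"
        }
        assert codon_table("NNK") == brute

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            codon_table("NNW")


class TestDiversity:
    def test_four_nnk_positions(self):
        d = diversity(design_library("KSPWFTTL", {1, 4, 6, 7}))
        assert d.nt_variants == 1_048_576
        assert d.stop_free_peptides == 160_000
        assert d.stop_containing_fraction == pytest.approx(1 - (31 / 32) ** 4)

    def test_zero_positions(self):
        d = diversity(design_library("KSPWFTTL", set()))
        assert d == (1, 1, 0.0)


class TestMergePairs:
    def test_exact_overlap_merges(self):
        rng = np.random.default_rng(1)
        frag = "".join(rng.choice(list("ACGT"), 250))
        r1, r2 = frag[:150], reverse_complement(frag[100:])
        m = merge_pairs(r1, r2, min_overlap=20)
        assert m.seq == frag

    def test_noisy_overlap_rejected(self):
        m = merge_pairs("A" * 50, reverse_complement("G" * 25 + "A" * 25), min_overlap=40)
        assert m.seq is None and m.reason == "no_overlap"

    def test_self_reverse_complement_identity(self):
        rng = np.random.default_rng(2)
        read = "".join(rng.choice(list("ACGT"), 120))
        m = merge_pairs(read, reverse_complement(read), min_overlap=20)
        assert m.seq == read

    def test_quality_resolves_disagreements(self):
        # single disagreement in a 30nt overlap; r2 has higher quality there
        a = "ACGTACGTACGTACGTACGTACGTACGTAC"
        b = "A" + a[1:]
        r2 = reverse_complement(b)
        q1 = "#" + "I" * 29
        q2 = "I" * 30
        m = merge_pairs(a, r2, min_overlap=20, q1=q1, q2=q2)
        assert m.seq == b  # r2's base wins at position 0
        m_tie = merge_pairs(a, r2, min_overlap=20)
        assert m_tie.seq == a  # ties go to r1


class TestExtractRegion:
    FL5 = "GGATCGGCTAGCATCG"
    FL3 = "CATGCTAGCTAGGACT"

    def test_exact_flanks(self):
        insert = "AAGTCTCCGTGGTTTACCACCCTG"  # 24 nt
        merged = "TT" + self.FL5 + insert + self.FL3 + "GG"
        out = extract_region(merged, self.FL5, self.FL3, expected_length=24)
        assert out.seq == insert

    def test_wrong_length_rejected(self):
        merged = self.FL5 + "A" * 23 + self.FL3
        assert extract_region(merged, self.FL5, self.FL3, expected_length=24).reason == "length"

    def test_missing_anchor_rejected(self):
        assert extract_region("A" * 60, self.FL5, self.FL3).reason == "no_anchor"

    def test_one_mismatch_anchor_tolerated(self):
        fl5 = "T" + self.FL5[1:]
        merged = fl5 + "A" * 24 + self.FL3
        assert extract_region(merged, self.FL5, self.FL3, max_mm=1,
                              expected_length=24).seq == "A" * 24


class TestTranslateFilter:
    DESIGN = design_library("KSPWFTTL", {1, 4, 6, 7}, "NNK")

    def test_mimotope_insert_accepted(self):
        from mimoseq.germline import encode_peptide

        pep, reason = translate_filter(encode_peptide("VSPWFNTL"), self.DESIGN)
        assert (pep, reason) == ("VSPWFNTL", None)

    def test_stop_codon_rejected(self):
        from mimoseq.germline import encode_peptide

        nt = "TAG" + encode_peptide("SPWFNTL")
        assert translate_filter(nt, self.DESIGN) == (None, "stop")

    def test_template_mismatch_rejected(self):
        from mimoseq.germline import encode_peptide

        assert translate_filter(encode_peptide("KAPWFTTL"), self.DESIGN) == \
            (None, "template_mismatch")

    def test_bad_length_is_error(self):
        with pytest.raises(ValueError):
            translate_filter("ACGT", self.DESIGN)


class TestTally:
    def test_exact_counts(self):
        t = tally_peptides(["AAAA", "AAAA", "CCCC"])
        assert t.counts == {"AAAA": 2, "CCCC": 1}

    def test_empty(self):
        assert tally_peptides([]).counts == {}

    def test_singleton_absorption(self):
        peps = ["VSPWFNTL"] * 100 + ["VSPWFNTI"]
        t = tally_peptides(peps, absorb_singletons=True)
        assert t.counts == {"VSPWFNTL": 101}

    def test_absorption_requires_large_neighbour(self):
        peps = ["VSPWFNTL"] * 5 + ["VSPWFNTI"]
        t = tally_peptides(peps, absorb_singletons=True)
        assert t.counts == {"VSPWFNTL": 5, "VSPWFNTI": 1}


class TestPreferenceMatrix:
    def test_weighted_position_frequencies(self):
        t = PeptideCountTable(0, {"VSPWFNTL": 3, "KSPWFTTL": 1})
        m = preference_matrix(t)
        assert m.weight(1, "V") == pytest.approx(0.75)
        assert m.weight(1, "K") == pytest.approx(0.25)
        assert m.weight(4, "W") == pytest.approx(1.0)

    def test_single_peptide_one_hot(self):
        m = preference_matrix(PeptideCountTable(0, {"KSPWFTTL": 7}))
        for i, aa in enumerate("KSPWFTTL", start=1):
            assert m.weight(i, aa) == 1.0

    def test_columns_sum_to_one(self):
        t = PeptideCountTable(0, {"AAAA": 2, "ACDE": 5, "WYWY": 1})
        m = preference_matrix(t)
        assert np.allclose(m.weights.sum(axis=1), 1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            preference_matrix(PeptideCountTable(0, {}))

    def test_pooled_counts_sum_rounds(self):
        a = PeptideCountTable(0, {"AA": 1, "CC": 2})
        b = PeptideCountTable(1, {"AA": 3})
        assert pooled_counts([a, b]).counts == {"AA": 4, "CC": 2}


class TestTrajectory:
    def test_fold_arithmetic_without_pseudocount(self):
        t0 = PeptideCountTable(0, {"AAAA": 10, "CCCC": 10})
        t1 = PeptideCountTable(1, {"AAAA": 30, "CCCC": 10})
        traj = enrichment_trajectory([t0, t1], pseudocount=0)
        assert traj["AAAA"].fold_changes[0] == pytest.approx(0.75 / 0.5)

    def test_pseudocount_keeps_folds_finite(self):
        t0 = PeptideCountTable(0, {"CCCC": 10})
        t1 = PeptideCountTable(1, {"CCCC": 5, "AAAA": 5})
        traj = enrichment_trajectory([t0, t1], pseudocount=1)
        assert math.isfinite(traj["AAAA"].cumulative_fold_enrichment)

    def test_single_round_rejected(self):
        with pytest.raises(ValueError):
            enrichment_trajectory([PeptideCountTable(0, {"AA": 1})])

    def test_two_peptide_closed_form(self):
        design = design_library("KSPWFTTL", {1})
        stringency, delta_e, rounds = 1.0, 0.5, 3
        truth = PlantedSelectionTruth(
            design=design,
            energies={"KSPWFTTL": 0.0, "VSPWFTTL": delta_e},
            stringency=stringency,
            depth_per_round=100_000,
            n_rounds=rounds,
            seed=17,
            initial_counts={"KSPWFTTL": 50_000, "VSPWFTTL": 50_000},
        )
        tables = simulate_selection_campaign(truth)
        traj = enrichment_trajectory(tables, pseudocount=0)
        ratio = (traj["KSPWFTTL"].cumulative_fold_enrichment
                 / traj["VSPWFTTL"].cumulative_fold_enrichment)
        expected = math.exp(stringency * delta_e * rounds)
        f = traj["KSPWFTTL"].trajectory[-1]
        sigma_f = math.sqrt(f * (1 - f) / truth.depth_per_round)
        # 3-sigma band propagated to the frequency ratio
        tol = 3 * sigma_f * (1 / f + 1 / (1 - f)) * math.sqrt(rounds)
        assert abs(ratio - expected) <= expected * tol


class TestRanking:
    def test_planted_binder_ranks_first(self):
        truth = default_selection_truth(seed=6)
        tables = simulate_selection_campaign(truth)
        ranked = rank_mimotopes(enrichment_trajectory(tables))
        assert ranked[0].peptide == truth.planted_binder

    def test_tie_break_is_lexicographic(self):
        t0 = PeptideCountTable(0, {"AAAA": 10, "CCCC": 10})
        t1 = PeptideCountTable(1, {"AAAA": 10, "CCCC": 10})
        ranked = rank_mimotopes(enrichment_trajectory([t0, t1], pseudocount=0))
        assert [c.peptide for c in ranked] == ["AAAA", "CCCC"]

    def test_single_peptide(self):
        t0 = PeptideCountTable(0, {"AAAA": 5})
        t1 = PeptideCountTable(1, {"AAAA": 9})
        assert rank_mimotopes(enrichment_trajectory([t0, t1]))[0].peptide == "AAAA"

    def test_rank_invariant_under_depth_rescaling(self):
        truth = default_selection_truth(seed=8, depth_per_round=20_000)
        tables = simulate_selection_campaign(truth)
        ranked = rank_mimotopes(enrichment_trajectory(tables, pseudocount=0))
        scaled = [
            PeptideCountTable(t.round_index, {p: 3 * c for p, c in t.counts.items()})
            for t in tables
        ]
        ranked_scaled = rank_mimotopes(enrichment_trajectory(scaled, pseudocount=0))
        assert [c.peptide for c in ranked[:50]] == [c.peptide for c in ranked_scaled[:50]]
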