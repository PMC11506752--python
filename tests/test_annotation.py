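"""Composition/skew profiling and gene-layout arithmetic."""

import math

import pytest
from hypothesis import given, strategies as st

import mitoprofile as mp
from mitoprofile.annotation import classify_stop
from mitoprofile.core import reverse_complement

# IN column as printed in the S. dorsalis annotation, in table order;
# the control region (printed ".") closes the circle with 0.
PRINTED_IN = {
    "tRNA-Phe": -1, "12S-rRNA": -1, "tRNA-Val": 0, "16S-rRNA": -1,
    "tRNA-Leu(L2)": 0, "ND1": 4, "tRNA-Ile": -2, "tRNA-Gln": -2,
    "tRNA-Met": 0, "ND2": -1, "tRNA-Trp": 0, "tRNA-Ala": 0, "tRNA-Asn": 37,
    "tRNA-Cys": -1, "tRNA-Tyr": 1, "COI": -1, "tRNA-Ser(S2)": 2,
    "tRNA-Asp": 7, "COII": -1, "tRNA-Lys": 1, "ATP8": -10, "ATP6": 0,
    "COIII": -1, "tRNA-Gly": 0, "ND3": -1, "tRNA-Arg": 1, "ND4L": -7,
    "ND4": -1, "tRNA-His": -1, "tRNA-Ser(S1)": 5, "tRNA-Leu(L1)": 0,
    "ND5": -4, "ND6": -1, "tRNA-Glu": 3, "CYTB": -1, "tRNA-Thr": -2,
    "tRNA-Pro": 0, "CR": 0,
}

random_dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestComposition:
    def test_simple_counts(self):
        comp = mp.base_composition("AATC")
        assert comp["percent_A"] == 50.0
        assert comp["percent_T"] == comp["percent_C"] == 25.0
        assert comp["percent_G"] == 0.0

    def test_equal_bases_symmetry(self):
        comp = mp.base_composition("ACGT")
        assert all(comp[f"percent_{b}"] == 25.0 for b in "ACGT")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mp.base_composition("")

    def test_ambiguity_counts_toward_length_only(self):
        comp = mp.base_composition("AANN")
        assert comp["percent_A"] == 50.0 and comp["percent_AT"] == 50.0
        assert sum(comp[f"percent_{b}"] for b in "ACGT") < 100.0


class TestSkew:
    def test_worked_example(self):
        at, gc = mp.at_gc_skew("AATC")
        assert at == pytest.approx(1 / 3)
        assert gc == -1.0

    def test_balanced_sequence_has_zero_skews(self):
        assert mp.at_gc_skew("ATATGCGC") == (0.0, 0.0)

    def test_zero_denominator_marker(self):
        at, gc = mp.at_gc_skew("GGCC")
        assert at is None and gc == 0.0

    @given(random_dna)
    def test_skew_bounds_and_revcomp_antisymmetry(self, seq):
        at, gc = mp.at_gc_skew(seq)
        rat, rgc = mp.at_gc_skew(reverse_complement(seq))
        for fwd, rev in ((at, rat), (gc, rgc)):
            if fwd is None:
                assert rev is None
            else:
                assert abs(fwd) <= 1
                assert rev == pytest.approx(-fwd)


class TestPartitions:
    def test_table_only_partition_totals(self, table1):
        lengths = mp.partition_lengths(table1)
        assert lengths["PCGs"][0] == 11427
        assert lengths["tRNAs"][0] == 1576
        assert lengths["rRNAs"][0] == 2670
        assert lengths["CR"][0] == 847
        # the study prints 69.10% for the PCG share; the raw quotient is
        # 11427/16541 = 69.08% -- assert the raw value to 0.05
        assert lengths["PCGs"][1] == pytest.approx(69.10, abs=0.05)
        assert round(lengths["CR"][1], 2) == 5.12

    def test_complete_partition_equals_whole_sequence_profile(self, sim_genome):
        profiles = {p.partition: p for p in mp.partition_profile(sim_genome)}
        whole = mp.base_composition(sim_genome.sequence)
        assert profiles["complete"].length == sim_genome.genome_length
        assert profiles["complete"].percent_at == pytest.approx(whole["percent_AT"])

    def test_partition_lengths_with_sequence(self, sim_genome):
        profiles = {p.partition: p for p in mp.partition_profile(sim_genome)}
        assert profiles["PCGs"].length == 11427
        assert profiles["PCGs"].percent_of_genome == pytest.approx(69.08, abs=0.01)
        assert profiles["CR"].length == 847

    def test_coding_vs_reference_strand_differ(self, sim_genome):
        coding = {p.partition: p for p in mp.partition_profile(sim_genome)}
        heavy = {p.partition: p
                 for p in mp.partition_profile(sim_genome, coding_strand=False)}
        # tRNA partition contains 8 light-strand genes: skews must differ
        assert coding["tRNAs"].at_skew != heavy["tRNAs"].at_skew

    def test_table_only_profile_rejected(self, table1):
        with pytest.raises(ValueError, match="sequence"):
            mp.partition_profile(table1)


class TestLayout:
    def test_full_table_reproduces_printed_in_column(self, table1):
        records, _ = mp.intergenic_layout(table1)
        for rec in records:
            assert rec.intergenic_nucleotides == PRINTED_IN[rec.gene_name], \
                rec.gene_name

    def test_overlap_summary_matches_printed_statistics(self, table1):
        _, summary = mp.intergenic_layout(table1)
        assert summary.overlap_count == 19
        assert summary.overlap_total_bp == 40
        assert summary.longest_overlap_bp == 10
        assert set(summary.longest_overlap_pair) == {"ATP8", "ATP6"}
        assert summary.longest_spacer_bp == 37
        assert summary.longest_spacer_gene == "tRNA-Asn"

    def test_adjacent_genes_have_zero_in(self):
        g = mp.AnnotatedMitogenome(genes=[
            mp.GeneRecord("a", mp.GeneKind.PCG, 1, 9),
            mp.GeneRecord("b", mp.GeneKind.PCG, 10, 20)], genome_length=20)
        records, summary = mp.intergenic_layout(g)
        assert records[0].intergenic_nucleotides == 0
        assert summary.overlap_count == 0

    def test_in_sum_closes_the_circle(self, table1):
        records, _ = mp.intergenic_layout(table1)
        total_in = sum(r.intergenic_nucleotides for r in records)
        total_size = sum(g.size(table1.genome_length) for g in table1.genes)
        assert total_in == table1.genome_length - total_size


class TestCodonEndpoints:
    @pytest.mark.parametrize("cds,expected,anomalous", [
        ("ATGAAATAA", "TAA", False),
        ("ATGAAATA", "TA-", False),   # polyadenylation-completed TA
        ("ATGAAAT", "T--", False),    # polyadenylation-completed T
        ("ATGAAAGC", "TA-", True),    # 2-nt tail that is not TA
        ("ATGAAACAC", "CAC", True),   # complete terminal that is not a stop
    ])
    def test_stop_classification(self, cds, expected, anomalous):
        assert classify_stop(cds) == (expected, anomalous)

    def test_simulated_genome_endpoints(self, sim_genome):
        eps = {e["gene"]: e for e in mp.codon_endpoints(sim_genome)}
        assert eps["COI"]["start_codon"] == "GTG"
        assert eps["ND1"]["start_codon"] == "ATG"
        assert eps["ND2"]["stop_codon"] == "T--"   # size 1045, mod 3 = 1
        assert eps["ATP6"]["stop_codon"] == "TA-"  # size 683, mod 3 = 2
        assert not eps["ND2"]["stop_anomalous"]

    def test_incomplete_stop_gene_set_matches_text(self, table1):
        # size-mod-3 classification alone identifies the seven genes the
        # study lists as polyadenylation-completed
        assert set(mp.incomplete_stop_genes(table1)) == \
            {"ND2", "ND3", "ND4", "COII", "COIII", "ATP6", "CYTB"}
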