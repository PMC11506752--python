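"""NG86 Ka/Ks, nucleotide diversity, sliding windows, K2P saturation."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

import mitoprofile as mp
from mitoprofile.evolution import kimura_2p

import oracles

SENSE_CODONS = sorted(c for c in mp.VERTEBRATE_MITO.codon_to_aa
                      if not mp.VERTEBRATE_MITO.is_stop(c))


def random_cds_pair(rng, n_codons=30):
    a = [rng.choice(SENSE_CODONS) for _ in range(n_codons)]
    b = [rng.choice(SENSE_CODONS) for _ in range(n_codons)]
    return "".join(a), "".join(b)


class TestSites:
    def test_glycine_third_position_fully_synonymous(self):
        # all three third-position changes of GGT are Gly->Gly
        s, n = mp.ng86_sites("GGT")
        assert s == pytest.approx(1.0)
        assert n == pytest.approx(2.0)

    def test_atg_reflects_ata_met(self):
        # under code 2, ATA is Met, so ATG has one synonymous third change
        # among the two that do not create a stop (ATA yes, ATT/ATC no;
        # none are stops)
        s, n = mp.ng86_sites("ATG")
        assert s == pytest.approx(1 / 3)

    @pytest.mark.parametrize("codon", ["TTA", "AGT", "TGG", "CGA"])
    def test_site_totals_bounded_by_three(self, codon):
        s, n = mp.ng86_sites(codon)
        assert 0 <= s and 0 <= n and s + n <= 3 + 1e-12

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            mp.ng86_sites("AGA")

    def test_sites_match_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            s, n = mp.ng86_sites(codon)
            so, no = oracles.site_counts(codon)
            assert s == pytest.approx(so) and n == pytest.approx(no), codon


class TestPairwise:
    def test_identical_pair_is_zero(self):
        cds = mp.random_cds(50, seed=1)
        r = mp.ng86_pair(cds, cds)
        assert r.ka == r.ks == 0.0 and r.ratio is None

    def test_purely_synonymous_mutant(self):
        cds = mp.random_cds(80, seed=2)
        mutant = mp.mutate_cds(cds, 5, 0, seed=3)
        r = mp.ng86_pair(cds, mutant)
        assert r.ka == 0.0 and r.ks > 0.0
        assert r.sd == pytest.approx(5.0) and r.nd == 0.0

    def test_symmetry(self):
        rng = random.Random(4)
        a, b = random_cds_pair(rng)
        r1, r2 = mp.ng86_pair(a, b), mp.ng86_pair(b, a)
        assert r1.sd == pytest.approx(r2.sd)
        assert r1.s_sites == pytest.approx(r2.s_sites)
        assert r1.ks == pytest.approx(r2.ks, abs=1e-12)

    def test_random_pairs_match_pathway_enumeration_oracle(self):
        rng = random.Random(5)
        for _ in range(50):
            a, b = random_cds_pair(rng)
            r = mp.ng86_pair(a, b)
            S, N, sd, nd = oracles.ng86(a, b)
            assert r.s_sites == pytest.approx(S)
            assert r.n_sites == pytest.approx(N)
            assert r.sd == pytest.approx(sd)
            assert r.nd == pytest.approx(nd)

    def test_pathway_average_conserves_total_differences(self):
        rng = random.Random(6)
        for _ in range(20):
            a, b = random_cds_pair(rng, 20)
            r = mp.ng86_pair(a, b)
            total = sum(x != y for x, y in zip(a, b))
            assert r.sd + r.nd == pytest.approx(total)

    def test_gapped_codons_dropped_pairwise(self):
        r = mp.ng86_pair("ATGAAA---", "ATGAAGCCC")
        assert r.codons_compared == 2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            mp.ng86_pair("ATGAAA", "ATGAAATTT")


class TestDiversity:
    def test_two_sequence_example(self):
        assert mp.nucleotide_diversity(
            ["AAAAAAAAAA", "AAAAAAAATT"]) == pytest.approx(0.2)

    def test_identical_alignment_is_zero(self):
        assert mp.nucleotide_diversity(["ACGT" * 5] * 4) == 0.0

    def test_four_sequences_equal_mean_pairwise(self):
        aln = ["ACGTACGTAC", "ACGTACGTAA", "ACGTACCTAC", "TCGTACGTAC"]
        assert mp.nucleotide_diversity(aln) == \
            pytest.approx(oracles.mean_pairwise_p_distance(aln))

    def test_complete_deletion_drops_gapped_columns(self):
        # gap column excluded for every pair, not only those with the gap
        aln = ["AAAA", "AAAT", "AA-T"]
        assert mp.nucleotide_diversity(aln, deletion="complete") == \
            pytest.approx(2 / 9) == pytest.approx(oracles.mean_pairwise_p_distance(aln))

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            mp.nucleotide_diversity(["ACGT"])

    @given(st.lists(st.text("ACGT", min_size=20, max_size=20),
                    min_size=2, max_size=6))
    @settings(max_examples=50)
    def test_pi_equals_mean_pairwise_p_distance(self, aln):
        assert mp.nucleotide_diversity(aln) == \
            pytest.approx(oracles.mean_pairwise_p_distance(aln))


class TestSlidingWindow:
    def test_default_window_layout(self):
        aln = ["A" * 250, "A" * 250]
        res = mp.sliding_window_pi(aln)
        assert [(s, e) for s, e, _ in res.windows] == \
            [(1, 200), (26, 225), (51, 250)]

    def test_window_equal_to_length_reproduces_global_pi(self):
        aln = ["ACGTACGTAC", "ACGTACGTAA"]
        res = mp.sliding_window_pi(aln, window=10, step=5)
        assert len(res.windows) == 1
        assert res.windows[0][2] == pytest.approx(res.pi)

    def test_oversized_window_truncates_with_flag(self):
        res = mp.sliding_window_pi(["ACGT", "ACGA"], window=10, step=5)
        assert res.truncated and res.windows == ((1, 4, pytest.approx(0.25)),)

    def test_argmax_window_overlaps_divergent_block(self):
        base = "A" * 500
        other = base[:300] + "TTTTTTTTTT" + base[310:]
        res = mp.sliding_window_pi([base, other])
        start, end, _ = max(res.windows, key=lambda w: w[2])
        assert start <= 310 and end >= 301  # window covers the block


class TestSaturation:
    def test_identical_pair(self):
        rec = mp.k2p_saturation(["ACGT" * 10] * 2)[0]
        assert (rec.p, rec.q, rec.k2p) == (0.0, 0.0, 0.0)

    def test_closed_form_value(self):
        assert kimura_2p(0.1, 0.05) == pytest.approx(0.17018, abs=5e-6)

    def test_transition_only_pair(self):
        # A<->G at half the sites: p=0.5 saturates the first log term? no:
        # 1-2p-q = 0 -> infinite distance marker
        a, b = "AG" * 10, "GA" * 10
        rec = mp.k2p_saturation([a, b])[0]
        assert rec.p == 1.0 and math.isinf(rec.k2p)

    def test_transition_only_simulation_recovers_closed_form(self):
        aln = mp.generate_alignment(2, 20000, 0.15, ti_tv_ratio=1000, seed=7)
        rec = mp.k2p_saturation(list(aln.values()))[0]
        assert rec.q <= 0.005
        assert rec.k2p == pytest.approx(-0.5 * math.log(1 - 2 * rec.p - rec.q)
                                        - 0.25 * math.log(1 - 2 * rec.q),
                                        rel=1e-9)

    def test_mean_k2p_monotone_in_divergence(self):
        means = []
        for d in (0.05, 0.15, 0.3):
            aln = mp.generate_alignment(4, 5000, d, seed=8)
            recs = mp.k2p_saturation(list(aln.values()))
            means.append(sum(r.k2p for r in recs) / len(recs))
        assert means[0] < means[1] < means[2]
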