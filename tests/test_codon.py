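"""Codon-level statistics: 4DTv, NG86 Ka/Ks, back-translation."""

import math
from itertools import permutations, product

import numpy as np
import pytest

from wgdkit.codon import (
    CODON_TO_AA,
    NUCLEOTIDES,
    CodonPairAlignment,
    backtranslate_to_codon_alignment,
    classify_fourfold_sites,
    compute_4dtv,
    compute_kaks_ng86,
    pathway_substitution_counts,
    synonymous_site_count,
)
from wgdkit.simulate import simulate_codon_pair

# A mixed codon set: 4-fold (Gly/Ala), 2-fold (Phe/Lys), 6-fold (Leu/Arg),
# non-degenerate (Met/Trp), and codons one step from a stop.
CODON_SET = [
    "TTT", "TTC", "TTA", "CTA", "ATG", "TGG",
    "GGA", "GGT", "GCC", "AAA", "AGA", "TCA", "TAT",
]


def oracle_pathway_counts(c1: str, c2: str):
    """Independent exhaustive enumeration of minimal substitution pathways."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results, blocked_results = [], []
    for order in permutations(diffs):
        cur, sd, nd, through_stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == "*":
                through_stop = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked_results if through_stop else results).append((sd, nd))
    use = results or blocked_results
    return (
        sum(r[0] for r in use) / len(use),
        sum(r[1] for r in use) / len(use),
    )


class TestAlignmentType:
    def test_rejects_unequal_lengths_and_partial_gaps(self):
        with pytest.raises(ValueError, match="lengths differ"):
            CodonPairAlignment("a", "b", "ATGAAA", "ATG")
        with pytest.raises(ValueError, match="divisible by 3"):
            CodonPairAlignment("a", "b", "ATGA", "ATGA")
        with pytest.raises(ValueError, match="whole-codon"):
            CodonPairAlignment("a", "b", "AT-AAA", "ATGAAA")

    def test_accepts_whole_codon_gaps(self):
        aln = CodonPairAlignment("a", "b", "ATG---AAA", "ATGCCCAAA")
        assert aln.n_columns == 3


class TestBacktranslate:
    def test_gap_expands_to_gap_codon(self):
        aln = backtranslate_to_codon_alignment(("M-K", "MGK"), "ATGAAA", "ATGGGAAAG")
        assert aln.seq1 == "ATG---AAA"
        assert aln.seq2 == "ATGGGAAAG"

    def test_identity_roundtrip(self):
        aln = backtranslate_to_codon_alignment(("MKW", "MKW"), "ATGAAATGG", "ATGAAGTGG")
        assert aln.seq1 == "ATGAAATGG"
        assert aln.seq2 == "ATGAAGTGG"

    def test_mismatch_reports_residue_position(self):
        with pytest.raises(ValueError, match="residue 2"):
            backtranslate_to_codon_alignment(("MA", "MA"), "ATGTTT", "ATGGCC")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            backtranslate_to_codon_alignment(("M*", "MW"), "ATGTAA", "ATGTGG")


class TestFourfoldSites:
    def brute_force_is_4d(self, c1, c2):
        if "-" in c1 + c2 or "N" in c1 + c2:
            return False
        if c1[:2] != c2[:2]:
            return False
        aas = {CODON_TO_AA[c1[:2] + n] for n in NUCLEOTIDES}
        aas |= {CODON_TO_AA[c2[:2] + n] for n in NUCLEOTIDES}
        return len(aas) == 1 and "*" not in aas

    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            ("GGA", "GGT", True),   # Gly, fourfold family
            ("TTT", "TTC", False),  # Phe, twofold third position
            ("GGA", "CGA", False),  # first positions differ
            ("CTA", "CTG", True),   # Leu via CT* fourfold prefix
        ],
    )
    def test_known_columns(self, c1, c2, expected):
        aln = CodonPairAlignment("a", "b", c1, c2)
        assert (classify_fourfold_sites(aln) == [0]) is expected

    def test_matches_enumeration_oracle_over_codon_grid(self):
        for c1, c2 in product(CODON_SET, repeat=2):
            aln = CodonPairAlignment("a", "b", c1, c2)
            got = classify_fourfold_sites(aln) == [0]
            assert got is self.brute_force_is_4d(c1, c2), (c1, c2)


class TestFourDTv:
    def test_identical_sequences_give_zero(self):
        aln = CodonPairAlignment("a", "b", "GGAGCT", "GGAGCT")
        est = compute_4dtv(aln)
        assert est.n_4d_sites == 2 and est.raw_4dtv == 0.0

    @pytest.mark.parametrize(
        "c2,expected", [("GGT", 1.0), ("GGG", 0.0)]
    )  # A<->T transversion; A<->G transition
    def test_single_site_transversion_vs_transition(self, c2, expected):
        est = compute_4dtv(CodonPairAlignment("a", "b", "GGA", c2))
        assert est.raw_4dtv == expected

    def test_correction_and_saturation(self):
        est = compute_4dtv(CodonPairAlignment("a", "b", "GGAGGC", "GGTGGC"), correct=True)
        assert est.raw_4dtv == 0.5 and est.corrected_4dtv is None
        est2 = compute_4dtv(
            CodonPairAlignment("a", "b", "GGAGGCGGG", "GGTGGCGGG"), correct=True
        )
        assert est2.corrected_4dtv == pytest.approx(-0.5 * math.log(1 - 2 / 3))

    def test_no_sites_flagged_undefined(self):
        est = compute_4dtv(CodonPairAlignment("a", "b", "ATG", "ATG"))
        assert est.n_4d_sites == 0 and est.raw_4dtv is None


class TestKaKsNG86:
    def test_identical_sequences(self):
        est = compute_kaks_ng86(CodonPairAlignment("a", "b", "ATGGGA" * 5, "ATGGGA" * 5))
        assert est.Ks == 0.0 and est.Ka == 0.0 and est.Sd == 0.0 and est.Nd == 0.0

    def test_worked_example_ten_phe_codons(self):
        # 10 TTT vs 9 TTT + TTC: S = 10/3, Sd = 1, pS = 0.3
        est = compute_kaks_ng86(CodonPairAlignment("a", "b", "TTT" * 10, "TTT" * 9 + "TTC"))
        assert est.S == pytest.approx(10 / 3)
        assert est.Sd == 1.0 and est.Nd == 0.0
        assert est.pS == pytest.approx(0.3)
        assert est.Ks == pytest.approx(-0.75 * math.log(0.6))
        assert est.Ka == 0.0

    def test_saturation_returns_undefined_not_error(self):
        est = compute_kaks_ng86(CodonPairAlignment("a", "b", "TTT", "TTC"))
        assert est.pS == pytest.approx(3.0)
        assert est.Ks is None and est.omega is None

    def test_no_usable_columns_is_an_error(self):
        with pytest.raises(ValueError, match="no usable codon columns"):
            compute_kaks_ng86(CodonPairAlignment("a", "b", "---", "ATG"))

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            aln, _ = simulate_codon_pair(0.4, 0.3, 50, rng=rng)
            est = compute_kaks_ng86(aln)
            assert est.S + est.N == pytest.approx(3 * est.n_codons_used, abs=1e-9)

    def test_symmetry_under_sequence_swap(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            aln, _ = simulate_codon_pair(0.5, 0.2, 60, rng=rng)
            fwd = compute_kaks_ng86(aln)
            rev = compute_kaks_ng86(
                CodonPairAlignment(aln.gene_id_2, aln.gene_id_1, aln.seq2, aln.seq1)
            )
            for f, r in [(fwd.Ks, rev.Ks), (fwd.Ka, rev.Ka), (fwd.Sd, rev.Sd)]:
                assert f == pytest.approx(r, abs=1e-12)

    def test_adding_synonymous_difference_increases_ks(self):
        base = "GGA" * 30
        prev = compute_kaks_ng86(CodonPairAlignment("a", "b", base, base)).Ks
        seq2 = list(base)
        for k in range(5):  # mutate third positions G->T progressively
            seq2[3 * k + 2] = "T"
            ks = compute_kaks_ng86(CodonPairAlignment("a", "b", base, "".join(seq2))).Ks
            assert ks > prev
            prev = ks

    def test_pathway_counts_match_exhaustive_oracle(self):
        for c1, c2 in product(CODON_SET, repeat=2):
            got = pathway_substitution_counts(c1, c2)
            want = oracle_pathway_counts(c1, c2)
            assert got == pytest.approx(want), (c1, c2)

    def test_multicodon_counts_are_additive_over_columns(self):
        # alignment-level Sd/Nd is the per-column sum, checked on 2-3 codon toys
        toys = [("TTTGGA", "TTCGGT"), ("ATGAAAGGA", "ATGAAGGGT")]
        for s1, s2 in toys:
            est = compute_kaks_ng86(CodonPairAlignment("a", "b", s1, s2))
            sd = nd = 0.0
            for i in range(0, len(s1), 3):
                d = oracle_pathway_counts(s1[i : i + 3], s2[i : i + 3])
                sd, nd = sd + d[0], nd + d[1]
            assert (est.Sd, est.Nd) == pytest.approx((sd, nd))

    def test_site_counts_hand_checked(self):
        assert synonymous_site_count("TTT") == pytest.approx(1 / 3)
        assert synonymous_site_count("GGA") == pytest.approx(1.0)
        assert synonymous_site_count("ATG") == 0.0
        with pytest.raises(ValueError):
            synonymous_site_count("TAA")


def test_4dtv_comonotonic_with_simulated_divergence():
    """Mean raw 4DTv rises with the simulated synonymous divergence."""
    rng = np.random.default_rng(23)
    means = []
    for d in (0.1, 0.4, 0.8):
        vals = []
        for _ in range(30):
            aln, _ = simulate_codon_pair(d, 0.2, 120, rng=rng)
            vals.append(compute_4dtv(aln).raw_4dtv)
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]
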