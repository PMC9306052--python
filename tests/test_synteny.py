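"""Collinear block chaining and homoeolog/paralog pair extraction."""

from itertools import combinations

import numpy as np
import pytest

from wgdkit.synteny import (
    GeneModel,
    HomologyHit,
    SyntenyBlock,
    SyntenyParams,
    build_gene_ranks,
    chain_collinear_blocks,
    collapse_tandem_hits,
    extract_homoeolog_pairs,
    extract_wgd_paralog_pairs,
    filter_hits,
)


def make_annotation(chrom_sizes: dict[str, int], prefix=""):
    genes = []
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            genes.append(GeneModel(f"{prefix}{chrom}g{i}", chrom, i * 100, i * 100 + 50))
    return build_gene_ranks(genes)


def hit(q, s, bits=100.0, evalue=1e-50):
    return HomologyHit(q, s, bits, evalue)


def brute_force_best_chain(anchors, params):
    """Exhaustive best single-chain score over all anchor subsets, both
    orientations (the independent oracle for the DP)."""
    best = 0.0
    n = len(anchors)
    for k in range(1, n + 1):
        for subset in combinations(range(n), k):
            pts = sorted(anchors[i] for i in subset)
            ra = [p[0] for p in pts]
            rb = [p[1] for p in pts]
            if len(set(ra)) < k or len(set(rb)) < k:
                continue
            for direction in (1, -1):
                sb = rb if direction == 1 else [-x for x in rb]
                if all(x < y for x, y in zip(sb, sb[1:])) and all(
                    y - x - 1 <= params.max_gap for x, y in zip(ra, ra[1:])
                ) and all(
                    abs(y - x) - 1 <= params.max_gap for x, y in zip(rb, rb[1:])
                ):
                    score = k * params.match_score + params.gap_penalty * (
                        sum(y - x - 1 for x, y in zip(ra, ra[1:]))
                        + sum(abs(y - x) - 1 for x, y in zip(rb, rb[1:]))
                    )
                    best = max(best, score)
    return best


class TestRanks:
    def test_ranks_follow_start_order(self):
        ann = build_gene_ranks(
            [
                GeneModel("g1", "chr1", 100, 150),
                GeneModel("g2", "chr1", 50, 80),
                GeneModel("g3", "chr1", 200, 260),
            ]
        )
        assert [ann.rank(g) for g in ("g1", "g2", "g3")] == [1, 0, 2]

    def test_ranks_independent_per_chromosome(self):
        ann = make_annotation({"chr1": 3, "chr2": 2})
        assert [ann.rank(f"chr2g{i}") for i in range(2)] == [0, 1]

    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_gene_ranks(
                [GeneModel("g", "chr1", 0, 10), GeneModel("g", "chr2", 0, 10)]
            )


class TestHitFilters:
    def test_evalue_and_top_n(self):
        hits = [hit("q", f"s{i}", bits=100 - i) for i in range(8)]
        hits.append(hit("q", "weak", evalue=1e-5))
        kept = filter_hits(hits, top_per_query=5)
        assert len(kept) == 5 and all(h.evalue <= 1e-10 for h in kept)

    def test_tandem_neighbours_collapsed(self):
        ann = make_annotation({"chr1": 20})
        hits = [hit("chr1g0", "chr1g3"), hit("chr1g0", "chr1g15")]
        kept = collapse_tandem_hits(hits, ann)
        assert [(h.query_id, h.subject_id) for h in kept] == [("chr1g0", "chr1g15")]


class TestChaining:
    def test_five_anchor_diagonal_forms_one_plus_block(self):
        ann_a = make_annotation({"A1": 10})
        ann_b = make_annotation({"B1": 20})
        hits = [hit(f"A1g{i}", f"B1g{10 + i}") for i in range(5)]
        blocks = chain_collinear_blocks(hits, ann_a, ann_b)
        assert len(blocks) == 1
        assert blocks[0].orientation == "plus" and len(blocks[0].anchors) == 5

    def test_four_anchor_diagonal_is_below_threshold(self):
        ann_a = make_annotation({"A1": 10})
        ann_b = make_annotation({"B1": 20})
        hits = [hit(f"A1g{i}", f"B1g{10 + i}") for i in range(4)]
        assert chain_collinear_blocks(hits, ann_a, ann_b) == []

    def test_six_anchor_antidiagonal_forms_minus_block(self):
        ann_a = make_annotation({"A1": 10})
        ann_b = make_annotation({"B1": 30})
        hits = [hit(f"A1g{i}", f"B1g{20 - i}") for i in range(6)]
        blocks = chain_collinear_blocks(hits, ann_a, ann_b)
        assert len(blocks) == 1 and blocks[0].orientation == "minus"

    def test_unknown_gene_id_rejected(self):
        ann = make_annotation({"A1": 5})
        with pytest.raises(ValueError, match="ghost"):
            chain_collinear_blocks([hit("A1g0", "ghost")], ann, ann)

    def test_gap_beyond_max_splits_chain(self):
        ann_a = make_annotation({"A1": 100})
        ann_b = make_annotation({"B1": 100})
        params = SyntenyParams(max_gap=5)
        hits = [hit(f"A1g{i}", f"B1g{i}") for i in range(5)]
        hits += [hit(f"A1g{i}", f"B1g{i}") for i in range(50, 55)]
        blocks = chain_collinear_blocks(hits, ann_a, ann_b, params)
        assert len(blocks) == 2

    def test_dp_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        params = SyntenyParams(min_block_genes=2, max_gap=25)
        ann_a = make_annotation({"A1": 40})
        ann_b = make_annotation({"B1": 40})
        for _ in range(25):
            n = int(rng.integers(4, 13))
            anchors = set()
            while len(anchors) < n:
                anchors.add((int(rng.integers(0, 40)), int(rng.integers(0, 40))))
            anchors = sorted(anchors)
            hits = [hit(f"A1g{ra}", f"B1g{rb}") for ra, rb in anchors]
            blocks = chain_collinear_blocks(hits, ann_a, ann_b, params)
            best_dp = max((b.score for b in blocks), default=0.0)
            assert best_dp == pytest.approx(brute_force_best_chain(anchors, params))

    def test_blocks_deterministic_under_hit_order(self):
        rng = np.random.default_rng(9)
        ann_a = make_annotation({"A1": 30, "A2": 30})
        ann_b = make_annotation({"B1": 30})
        hits = [hit(f"A1g{i}", f"B1g{i}") for i in range(8)]
        hits += [hit(f"A2g{i}", f"B1g{20 - i}") for i in range(7)]
        ref = chain_collinear_blocks(hits, ann_a, ann_b)
        for _ in range(5):
            shuffled = list(hits)
            rng.shuffle(shuffled)
            got = chain_collinear_blocks(shuffled, ann_a, ann_b)
            assert [(b.chrom_a, b.chrom_b, b.orientation, b.anchors) for b in got] == [
                (b.chrom_a, b.chrom_b, b.orientation, b.anchors) for b in ref
            ]


class TestPairExtraction:
    def block(self, chrom_a, chrom_b, anchors, score=100.0):
        return SyntenyBlock("b0", chrom_a, chrom_b, anchors, "plus", score)

    def test_cross_subgenome_anchors_oriented_a_first(self):
        blk = self.block("chrB1", "chrA1", [(f"b{i}", f"a{i}") for i in range(5)])
        pairs = extract_homoeolog_pairs([blk], {"chrA1": "A", "chrB1": "B"})
        assert pairs == [(f"a{i}", f"b{i}") for i in range(5)]

    def test_same_subgenome_block_contributes_nothing(self):
        blk = self.block("chrA1", "chrA2", [("x", "y")] * 5)
        assert extract_homoeolog_pairs([blk], {"chrA1": "A", "chrA2": "A"}) == []

    def test_duplicate_pair_keeps_higher_scoring_block(self):
        b1 = self.block("chrA1", "chrB1", [("a0", "b0")], score=10)
        b2 = self.block("chrA1", "chrB1", [("a0", "b0")], score=99)
        pairs = extract_homoeolog_pairs([b1, b2], {"chrA1": "A", "chrB1": "B"})
        assert pairs == [("a0", "b0")]

    def test_unlabeled_chromosome_rejected(self):
        blk = self.block("chrA1", "chrX", [("a", "x")])
        with pytest.raises(ValueError, match="chrX"):
            extract_homoeolog_pairs([blk], {"chrA1": "A"})

    def test_wgd_triple_definition(self):
        within = [self.block("fA", "fB", [("a1", "b1")])]
        outgroup = [self.block("fA", "Ot1", [("a1", "o1")]),
                    self.block("fB", "Ot1", [("b1", "o1")])]
        assert extract_wgd_paralog_pairs(within, outgroup) == [("a1", "b1", "o1")]

    def test_outgroup_gene_with_three_copies_excluded(self):
        within = [self.block("fA", "fB", [("a1", "b1")])]
        outgroup = [
            self.block("fA", "Ot1", [("a1", "o1")]),
            self.block("fB", "Ot1", [("b1", "o1"), ("c1", "o1")]),
        ]
        assert extract_wgd_paralog_pairs(within, outgroup) == []


class TestPlantedRecovery:
    def test_planted_anchor_recovery_at_least_95_percent(self, default_bundle, default_blocks):
        anchors = {frozenset(p) for b in default_blocks["self"] for p in b.anchors}
        planted = {frozenset(p) for p in default_bundle.truth.homoeolog_pairs}
        recovery = len(anchors & planted) / len(planted)
        assert recovery >= 0.95

    def test_block_invariants_hold_on_fixture(self, default_blocks):
        # validate_block already runs inside chaining; spot-check orientation
        for blk in default_blocks["self"]:
            assert len(blk.anchors) >= 5
            assert blk.orientation in ("plus", "minus")
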