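"""Collinear (synteny) block detection and homoeolog/paralog pairing.

Blocks are chained from homology hits by dynamic programming over gene
rank coordinates, separately for the two diagonal orientations, in the
style of MCScanX. A block needs at least ``min_block_genes`` anchors
(default 5) to be reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneModel",
    "HomologyHit",
    "SyntenyBlock",
    "SyntenyParams",
    "RankedAnnotation",
    "build_gene_ranks",
    "filter_hits",
    "collapse_tandem_hits",
    "chain_collinear_blocks",
    "extract_homoeolog_pairs",
    "extract_wgd_paralog_pairs",
    "validate_block",
]


@dataclass
class GeneModel:
    """A gene with 0-based half-open coordinates and a per-chromosome rank."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    identity_pct: float = 100.0


@dataclass
class SyntenyParams:
    min_block_genes: int = 5
    max_gap: int = 25
    match_score: float = 50.0
    gap_penalty: float = -1.0

    def __post_init__(self) -> None:
        if self.min_block_genes < 2:
            raise ValueError("min_block_genes must be >= 2")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


@dataclass
class SyntenyBlock:
    block_id: str
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]
    orientation: str  # "plus" | "minus"
    score: float


@dataclass
class RankedAnnotation:
    """Genes indexed by id, with dense ranks along each chromosome."""

    genes: dict[str, GeneModel]
    chromosomes: dict[str, list[str]] = field(default_factory=dict)

    def rank(self, gene_id: str) -> int:
        return self.genes[gene_id].rank

    def chromosome(self, gene_id: str) -> str:
        return self.genes[gene_id].chromosome

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


def build_gene_ranks(annotation: Iterable[GeneModel]) -> RankedAnnotation:
    """Sort genes by (chromosome, start, gene_id) and assign dense ranks."""
    genes: dict[str, GeneModel] = {}
    for g in annotation:
        if g.gene_id in genes:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        genes[g.gene_id] = g
    chroms: dict[str, list[str]] = {}
    ordered = sorted(genes.values(), key=lambda g: (g.chromosome, g.start, g.gene_id))
    for g in ordered:
        chroms.setdefault(g.chromosome, []).append(g.gene_id)
    for ids in chroms.values():
        for r, gid in enumerate(ids):
            genes[gid].rank = r
    return RankedAnnotation(genes, chroms)


def filter_hits(
    hits: Iterable[HomologyHit],
    max_evalue: float = 1e-10,
    top_per_query: int = 5,
) -> list[HomologyHit]:
    """E-value cutoff then best-N hits per query by descending bitscore."""
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.evalue <= max_evalue:
            by_query.setdefault(h.query_id, []).append(h)
    out: list[HomologyHit] = []
    for q in sorted(by_query):
        ranked = sorted(by_query[q], key=lambda h: (-h.bitscore, h.subject_id))
        out.extend(ranked[:top_per_query])
    return out


def collapse_tandem_hits(
    hits: Iterable[HomologyHit],
    ranks: RankedAnnotation,
    max_rank_distance: int = 5,
) -> list[HomologyHit]:
    """Drop within-genome hits between close neighbours on one chromosome.

    Hits whose two genes sit within ``max_rank_distance`` ranks on the same
    chromosome are tandem-array artefacts, not WGD signal.
    """
    out = []
    for h in hits:
        ga, gb = ranks.genes[h.query_id], ranks.genes[h.subject_id]
        if ga.chromosome == gb.chromosome and abs(ga.rank - gb.rank) <= max_rank_distance:
            continue
        out.append(h)
    return out


def _chain_dp(
    anchors: list[tuple[int, int, str, str]], params: SyntenyParams
) -> tuple[float, list[int]]:
    """Best chain (score, indices) over anchors with strictly increasing
    ranks on both axes and per-axis rank gaps <= max_gap."""
    n = len(anchors)
    best: tuple[float, list[int]] = (float("-inf"), [])
    if n == 0:
        return best
    score = [params.match_score] * n
    prev = [-1] * n
    for j in range(n):
        ra_j, rb_j = anchors[j][0], anchors[j][1]
        for i in range(j):
            ra_i, rb_i = anchors[i][0], anchors[i][1]
            if ra_i >= ra_j or rb_i >= rb_j:
                continue
            gap_a, gap_b = ra_j - ra_i - 1, rb_j - rb_i - 1
            if gap_a > params.max_gap or gap_b > params.max_gap:
                continue
            cand = score[i] + params.match_score + params.gap_penalty * (gap_a + gap_b)
            if cand > score[j] or (cand == score[j] and prev[j] == -1):
                score[j] = cand
                prev[j] = i
    end = max(range(n), key=lambda j: (score[j], -j))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    chain.reverse()
    return score[chain[-1]], chain


def chain_collinear_blocks(
    hits: Sequence[HomologyHit],
    ranks_a: RankedAnnotation,
    ranks_b: RankedAnnotation | None,
    params: SyntenyParams | None = None,
    within: bool = False,
) -> list[SyntenyBlock]:
    """Chain hits into collinear blocks per chromosome pair and orientation.

    ``within=True`` treats the hits as genome-vs-self: self-hits are removed
    and (x, y)/(y, x) duplicates are collapsed. Overlapping chains are
    resolved greedily by descending score (then anchor count, then
    lexicographic chromosome pair); blocks shorter than
    ``params.min_block_genes`` are discarded.
    """
    params = params or SyntenyParams()
    if ranks_b is None:
        ranks_b = ranks_a
        within = True

    pair_anchors: dict[tuple[str, str], set[tuple[int, int, str, str]]] = {}
    for h in hits:
        if h.query_id not in ranks_a:
            raise ValueError(f"unknown gene id in hits: {h.query_id!r}")
        if h.subject_id not in ranks_b:
            raise ValueError(f"unknown gene id in hits: {h.subject_id!r}")
        ga, gb = ranks_a.genes[h.query_id], ranks_b.genes[h.subject_id]
        if within:
            if ga.gene_id == gb.gene_id:
                continue
            # canonical orientation so (x,y) and (y,x) coincide
            if (gb.chromosome, gb.rank) < (ga.chromosome, ga.rank):
                ga, gb = gb, ga
        key = (ga.chromosome, gb.chromosome)
        pair_anchors.setdefault(key, set()).add((ga.rank, gb.rank, ga.gene_id, gb.gene_id))

    candidates: list[SyntenyBlock] = []
    for (ca, cb) in sorted(pair_anchors):
        anchors = sorted(pair_anchors[(ca, cb)])
        for orientation in ("plus", "minus"):
            if orientation == "minus":
                oriented = sorted((ra, -rb, a, b) for ra, rb, a, b in anchors)
            else:
                oriented = anchors
            remaining = list(oriented)
            while len(remaining) >= params.min_block_genes:
                score, idx = _chain_dp(remaining, params)
                if len(idx) < params.min_block_genes:
                    break
                chosen = [remaining[i] for i in idx]
                blk = SyntenyBlock(
                    "", ca, cb, [(a, b) for _, _, a, b in chosen], orientation, score
                )
                blk._tuples = chosen  # type: ignore[attr-defined]
                candidates.append(blk)
                used = set(idx)
                used_genes = {g for _, _, a, b in chosen for g in (a, b)}
                remaining = [
                    t
                    for i, t in enumerate(remaining)
                    if i not in used and t[2] not in used_genes and t[3] not in used_genes
                ]

    # greedy resolution of chains that share anchors across orientations;
    # pruned chains are re-run through the DP so gap invariants still hold
    candidates.sort(
        key=lambda b: (-b.score, -len(b.anchors), b.chrom_a, b.chrom_b, b.orientation)
    )
    blocks: list[SyntenyBlock] = []
    used_pairs: set[frozenset[str]] = set()
    for blk in candidates:
        surviving = [
            t for t in blk._tuples  # type: ignore[attr-defined]
            if frozenset((t[2], t[3])) not in used_pairs
        ]
        if len(surviving) < params.min_block_genes:
            continue
        score, idx = _chain_dp(surviving, params)
        if len(idx) < params.min_block_genes:
            continue
        chosen = [surviving[i] for i in idx]
        blk.anchors = [(a, b) for _, _, a, b in chosen]
        blk.score = score
        used_pairs.update(frozenset(p) for p in blk.anchors)
        blk.block_id = f"b{len(blocks):04d}"
        blocks.append(blk)
        validate_block(blk, ranks_a, ranks_b, params)
    return blocks


def validate_block(
    block: SyntenyBlock,
    ranks_a: RankedAnnotation,
    ranks_b: RankedAnnotation,
    params: SyntenyParams,
) -> None:
    """Assert the SyntenyBlock invariants; raises ``AssertionError``."""
    assert len(block.anchors) >= params.min_block_genes, block.block_id
    ra = [ranks_a.rank(a) for a, _ in block.anchors]
    rb = [ranks_b.rank(b) for _, b in block.anchors]
    assert all(x < y for x, y in zip(ra, ra[1:])), "ranks_a not increasing"
    if block.orientation == "plus":
        assert all(x < y for x, y in zip(rb, rb[1:])), "ranks_b not increasing"
    else:
        assert all(x > y for x, y in zip(rb, rb[1:])), "ranks_b not decreasing"
    for x, y in zip(ra, ra[1:]):
        assert y - x - 1 <= params.max_gap, "gap on chrom_a exceeds max_gap"
    for x, y in zip(rb, rb[1:]):
        assert abs(y - x) - 1 <= params.max_gap, "gap on chrom_b exceeds max_gap"


def extract_homoeolog_pairs(
    blocks: Iterable[SyntenyBlock],
    subgenome_map: Mapping[str, str],
) -> list[tuple[str, str]]:
    """Anchor pairs from blocks linking different subgenomes, A-member first.

    Duplicate unordered pairs from multiple blocks collapse to the
    assignment of the higher-scoring block.
    """
    best: dict[frozenset[str], tuple[float, tuple[str, str]]] = {}
    for blk in blocks:
        try:
            sub_a, sub_b = subgenome_map[blk.chrom_a], subgenome_map[blk.chrom_b]
        except KeyError as exc:
            raise ValueError(f"chromosome without subgenome label: {exc.args[0]!r}")
        if sub_a == sub_b:
            continue
        for ga, gb in blk.anchors:
            pair = (ga, gb) if sub_a == "A" else (gb, ga)
            key = frozenset(pair)
            if key not in best or blk.score > best[key][0]:
                best[key] = (blk.score, pair)
    return sorted(pair for _, pair in best.values())


def extract_wgd_paralog_pairs(
    within_blocks: Iterable[SyntenyBlock],
    outgroup_blocks: Iterable[SyntenyBlock],
) -> list[tuple[str, str, str]]:
    """WGD-retained duplicate pairs anchored by a single outgroup gene.

    A triple ``(copy1, copy2, outgroup_gene)`` is reported when the outgroup
    gene anchors to exactly two distinct focal genes in ``outgroup_blocks``
    (focal gene first in those anchors) and the two focal genes themselves
    form an anchor in ``within_blocks``.
    """
    focal_by_outgroup: dict[str, set[str]] = {}
    for blk in outgroup_blocks:
        for focal, og in blk.anchors:
            focal_by_outgroup.setdefault(og, set()).add(focal)
    within_pairs = {
        frozenset(p) for blk in within_blocks for p in blk.anchors
    }
    triples = []
    for og in sorted(focal_by_outgroup):
        copies = sorted(focal_by_outgroup[og])
        if len(copies) != 2:
            continue
        if frozenset(copies) in within_pairs:
            triples.append((copies[0], copies[1], og))
    # each focal pair reported once
    seen: set[frozenset[str]] = set()
    out = []
    for c1, c2, og in triples:
        key = frozenset((c1, c2))
        if key in seen:
            continue
        seen.add(key)
        out.append((c1, c2, og))
    return out
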