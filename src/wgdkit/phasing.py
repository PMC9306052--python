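"""Outgroup-guided subgenome phasing of an allotetraploid.

Each pseudochromosome of the focal genome is assigned to subgenome A or B
from its synonymous-site distance (mean NG86 Ks over single-copy syntenic
orthologs) to the outgroup chromosomes: outgroup chromosomes are matched to
their two focal partners by a global minimum-cost assignment, and within
each matched pair the focal chromosome closer to the outgroup joins A.
A neighbor-joining tree over the chromosome distance matrix provides the
phylogenetic view of the same structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .codon import CodonPairAlignment, compute_kaks_ng86

__all__ = [
    "ChromosomeDistanceMatrix",
    "PhasingResult",
    "chromosome_distances",
    "build_nj_tree",
    "assign_subgenomes",
]


@dataclass
class ChromosomeDistanceMatrix:
    """Symmetric chromosome-level distance matrix; NaN marks missing pairs."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(self.d - self.d.T)) if n else 0.0
        if asym > 1e-12:
            raise ValueError("matrix not symmetric")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.d).any()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def _pair_distance(values) -> float:
    """Mean Ks of a chromosome pair; alignments are reduced with NG86 and
    undefined (saturated) estimates are excluded."""
    ks = []
    for v in values:
        if isinstance(v, CodonPairAlignment):
            v = compute_kaks_ng86(v).Ks
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        ks.append(float(v))
    return float(np.mean(ks)) if ks else float("nan")


def chromosome_distances(
    groups: dict[tuple[str, str], list],
    min_genes: int = 10,
    max_missing_fraction: float = 0.10,
) -> ChromosomeDistanceMatrix:
    """Chromosome distance matrix from per-pair gene alignment (or Ks) lists.

    *groups* maps (chrom_1, chrom_2) to a list of ``CodonPairAlignment`` or
    precomputed Ks values. Provided pairs with fewer than *min_genes* usable
    genes are flagged missing; if more than *max_missing_fraction* of the
    provided pairs are missing the matrix is rejected. Chromosome pairs that
    were never provided (no synteny) stay NaN.
    """
    labels = sorted({c for pair in groups for c in pair})
    n = len(labels)
    idx = {c: i for i, c in enumerate(labels)}
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    acc: dict[tuple[int, int], list[float]] = {}
    counts: dict[tuple[int, int], int] = {}
    for (ca, cb), values in groups.items():
        i, j = sorted((idx[ca], idx[cb]))
        if i == j:
            continue
        acc.setdefault((i, j), []).append(_pair_distance(values))
        counts[(i, j)] = counts.get((i, j), 0) + sum(
            1
            for v in values
            if not (v is None or (isinstance(v, float) and np.isnan(v)))
        )
    n_missing = 0
    for (i, j), dists in acc.items():
        if counts[(i, j)] < min_genes or all(np.isnan(x) for x in dists):
            n_missing += 1
            continue
        d[i, j] = d[j, i] = float(np.nanmean(dists))
    if acc and n_missing / len(acc) > max_missing_fraction:
        raise ValueError(
            f"{n_missing}/{len(acc)} provided chromosome pairs below "
            f"min_genes={min_genes}"
        )
    return ChromosomeDistanceMatrix(labels, d)


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner})"


def build_nj_tree(matrix: ChromosomeDistanceMatrix) -> str:
    """Neighbor-joining (Saitou–Nei) tree as a Newick string.

    Standard Q-matrix agglomeration with the Saitou–Nei branch-length
    formulas; negative branch lengths are clamped to zero with the deficit
    moved to the sister branch. The final three lineages are joined at an
    unresolved root via the three-point formulas, so the output is the usual
    unrooted (trifurcating) Newick.
    """
    if not matrix.is_complete:
        raise ValueError("NJ requires a complete distance matrix")
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("NJ requires at least 3 labels")
    nodes: list[_Node] = [_Node(label=lab) for lab in matrix.labels]
    d = matrix.d.astype(float).copy()
    active = list(range(n))

    def clamp(bi: float, bj: float) -> tuple[float, float]:
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        return bi, max(bj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, nodes[i].label or "", nodes[j].label or "")
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        bi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        bj = d[i, j] - bi
        bi, bj = clamp(bi, bj)
        new = _Node(children=[(nodes[i], bi), (nodes[j], bj)])
        # distances from the new node to every other active node
        dnew = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            dnew[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(dnew) - 1] = dnew[:-1]
        d[: len(dnew) - 1, -1] = dnew[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    bi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    bj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    bk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    parts = []
    for node, bl in ((nodes[i], bi), (nodes[j], bj), (nodes[k], bk)):
        parts.append(f"{node.newick()}:{max(bl, 0.0):.6g}")
    return f"({','.join(parts)});"


@dataclass
class PhasingResult:
    assignment: dict[str, str]  # focal chromosome -> "A" | "B"
    partner: dict[str, str]  # focal chromosome -> outgroup chromosome
    margin: dict[str, float]  # |d_closer - d_farther| supporting the call
    ambiguous: set[str] = field(default_factory=set)
    low_confidence: set[str] = field(default_factory=set)
    strict: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chromosome": c,
                "subgenome": self.assignment[c],
                "partner": self.partner.get(c, ""),
                "margin": self.margin.get(c, float("nan")),
                "confidence": (
                    "ambiguous"
                    if c in self.ambiguous
                    else "low" if c in self.low_confidence else "ok"
                ),
            }
            for c in sorted(self.assignment)
        ]
        return pd.DataFrame(rows)


def assign_subgenomes(
    matrix: ChromosomeDistanceMatrix,
    outgroup_labels: set[str],
    seed_partition: set[str] | None = None,
    block_sharing: dict[frozenset[str], float] | None = None,
    margin_threshold: float = 0.01,
) -> PhasingResult:
    """Phase focal chromosomes into subgenomes A and B.

    In strict mode (``#focal == 2 * #outgroup``) every outgroup chromosome is
    matched to its two nearest focal chromosomes by a global assignment that
    minimises total distance; within each matched pair the closer focal
    chromosome joins A. Missing distances count as effectively infinite.
    When *block_sharing* (shared-synteny weight per unordered focal-chromosome
    pair) is supplied, pairs whose margin falls below *margin_threshold* are
    re-oriented to maximise within-subgenome sharing with the confidently
    phased pairs. *seed_partition* names chromosomes that must end up in A,
    flipping the global labels if needed (partners and margins are unchanged).
    """
    focal = sorted(set(matrix.labels) - set(outgroup_labels))
    outgroup = sorted(set(outgroup_labels) & set(matrix.labels))
    if not focal or not outgroup:
        raise ValueError("need both focal and outgroup chromosomes in the matrix")

    finite = matrix.d[np.isfinite(matrix.d)]
    big = (np.max(finite) if finite.size else 1.0) * 1e3 + 1.0

    def dist(a: str, b: str) -> float:
        v = matrix.get(a, b)
        return big if np.isnan(v) else v

    strict = len(focal) == 2 * len(outgroup)
    assignment: dict[str, str] = {}
    partner: dict[str, str] = {}
    margin: dict[str, float] = {}
    ambiguous: set[str] = set()

    if strict:
        # slots: each outgroup chromosome appears twice
        slots = [og for og in outgroup for _ in range(2)]
        cost = np.array([[dist(f, og) for og in slots] for f in focal])
        rows, cols = linear_sum_assignment(cost)
        by_outgroup: dict[str, list[str]] = {}
        for r, c in zip(rows, cols):
            partner[focal[r]] = slots[c]
            by_outgroup.setdefault(slots[c], []).append(focal[r])
        for og, pair in by_outgroup.items():
            pair = sorted(pair, key=lambda f: (dist(f, og), f))
            closer, farther = pair
            m = abs(dist(farther, og) - dist(closer, og))
            assignment[closer], assignment[farther] = "A", "B"
            margin[closer] = margin[farther] = m
            if m == 0:
                ambiguous.update(pair)
    else:
        warnings.warn(
            "focal chromosome count is not twice the outgroup count; "
            "falling back to per-chromosome nearest-outgroup labeling",
            stacklevel=2,
        )
        for f in focal:
            og = min(outgroup, key=lambda o: (dist(f, o), o))
            partner[f] = og
        for og in outgroup:
            members = sorted(
                (f for f in focal if partner[f] == og),
                key=lambda f: (dist(f, og), f),
            )
            for k, f in enumerate(members):
                assignment[f] = "A" if k == 0 else "B"
                margin[f] = (
                    abs(dist(members[1], og) - dist(members[0], og))
                    if len(members) > 1
                    else float("nan")
                )

    # refine ambiguous/low-margin pairs with block sharing, if supplied
    if block_sharing and strict:
        fixed = {f for f in focal if margin[f] >= margin_threshold}
        free_pairs = sorted(
            {partner[f] for f in focal if f not in fixed}
        )
        by_outgroup = {}
        for f in focal:
            by_outgroup.setdefault(partner[f], []).append(f)

        def sharing(labels: dict[str, str]) -> float:
            total = 0.0
            for key, w in block_sharing.items():
                a, b = sorted(key)
                if labels.get(a) and labels.get(a) == labels.get(b):
                    total += w
            return total

        best_labels, best_val = dict(assignment), sharing(assignment)
        if len(free_pairs) <= 12:
            for flips in product((False, True), repeat=len(free_pairs)):
                trial = dict(assignment)
                for og, flip in zip(free_pairs, flips):
                    if flip:
                        x, y = sorted(by_outgroup[og])
                        trial[x], trial[y] = trial[y], trial[x]
                val = sharing(trial)
                if val > best_val:
                    best_labels, best_val = trial, val
        assignment = best_labels

    if seed_partition is not None:
        in_a = sum(1 for f in seed_partition if assignment.get(f) == "A")
        in_b = sum(1 for f in seed_partition if assignment.get(f) == "B")
        if in_b > in_a:
            assignment = {
                f: ("A" if s == "B" else "B") for f, s in assignment.items()
            }

    low_conf = {
        f
        for f in focal
        if not np.isnan(margin.get(f, float("nan"))) and margin[f] < margin_threshold
    }
    return PhasingResult(assignment, partner, margin, ambiguous, low_conf, strict)
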