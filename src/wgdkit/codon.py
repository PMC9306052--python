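"""Pairwise codon-level evolutionary statistics.

Implements the two classical divergence proxies used to date whole-genome
duplications from coding sequence:

* **4DTv** — the proportion of transversions at third positions of
  fourfold-degenerate codon sites, optionally corrected for multiple hits
  with the HKY-style transform ``-0.5 * ln(1 - 2 * raw)``.
* **Ka/Ks** — Nei–Gojobori (1986) counting with equal-weight averaging over
  all minimal substitution pathways (pathways through stop codons excluded)
  and Jukes–Cantor correction ``d = -(3/4) ln(1 - (4/3) p)``.

Saturation (``p >= 3/4`` for JC, ``raw >= 1/2`` for the 4DTv transform) is a
first-class *undefined* outcome represented as ``None``; downstream code must
filter it explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterator

from Bio.Data import CodonTable as _CodonTable

__all__ = [
    "CodonPairAlignment",
    "FourDTvEstimate",
    "KaKsEstimate",
    "backtranslate_to_codon_alignment",
    "classify_fourfold_sites",
    "compute_4dtv",
    "compute_kaks_ng86",
    "is_transversion",
    "synonymous_site_count",
]

NUCLEOTIDES = "ACGT"
GAP_CODON = "---"
_PURINES = frozenset("AG")

_table = _CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, with '*' for the three stop codons
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
CODON_TO_AA.update({c: "*" for c in _table.stop_codons})

#: two-base prefixes whose four codons all encode the same amino acid
FOURFOLD_PREFIXES: frozenset[str] = frozenset(
    p
    for p in (a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)
    if len({CODON_TO_AA[p + n] for n in NUCLEOTIDES}) == 1
)


def is_transversion(a: str, b: str) -> bool:
    """True when *a* and *b* are a purine/pyrimidine pair (A/G vs C/T)."""
    return (a in _PURINES) != (b in _PURINES)


@dataclass(frozen=True)
class CodonPairAlignment:
    """Two gap-aligned, in-frame coding sequences.

    Gaps occur only in whole-codon units; the alphabet is ``{A,C,G,T,-,N}``.
    """

    gene_id_1: str
    gene_id_2: str
    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        s1, s2 = self.seq1.upper(), self.seq2.upper()
        object.__setattr__(self, "seq1", s1)
        object.__setattr__(self, "seq2", s2)
        if len(s1) != len(s2):
            raise ValueError(
                f"aligned lengths differ: {len(s1)} vs {len(s2)} "
                f"({self.gene_id_1}/{self.gene_id_2})"
            )
        if len(s1) % 3 != 0:
            raise ValueError(f"alignment length {len(s1)} not divisible by 3")
        allowed = set("ACGTN-")
        bad = (set(s1) | set(s2)) - allowed
        if bad:
            raise ValueError(f"illegal characters in alignment: {sorted(bad)}")
        for seq in (s1, s2):
            for cod in (seq[i : i + 3] for i in range(0, len(seq), 3)):
                if "-" in cod and cod != GAP_CODON:
                    raise ValueError(f"gap not in whole-codon units: {cod!r}")

    @property
    def n_columns(self) -> int:
        return len(self.seq1) // 3

    def codon_columns(self) -> Iterator[tuple[int, str, str]]:
        """Yield ``(column_index, codon1, codon2)`` for every codon column."""
        for i in range(self.n_columns):
            yield i, self.seq1[3 * i : 3 * i + 3], self.seq2[3 * i : 3 * i + 3]


@dataclass(frozen=True)
class FourDTvEstimate:
    n_4d_sites: int
    n_transversions: int
    raw_4dtv: float | None
    corrected_4dtv: float | None


@dataclass(frozen=True)
class KaKsEstimate:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    omega: float | None
    n_codons_used: int


def _translate(cds: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def backtranslate_to_codon_alignment(
    protein_alignment: tuple[str, str],
    cds1: str,
    cds2: str,
    gene_id_1: str = "seq1",
    gene_id_2: str = "seq2",
) -> CodonPairAlignment:
    """Map a gapped protein alignment onto its source coding sequences.

    Each amino-acid column expands to the corresponding codon; protein gaps
    expand to ``---``. The CDS must translate (standard code) to the ungapped
    protein; internal stops or translation mismatches are rejected with the
    position of the first discordance.
    """
    prot1, prot2 = (p.upper() for p in protein_alignment)
    if len(prot1) != len(prot2):
        raise ValueError("protein alignment rows have unequal length")
    out = []
    for prot, cds, gid in ((prot1, cds1.upper(), gene_id_1), (prot2, cds2.upper(), gene_id_2)):
        ungapped = prot.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{gid}: CDS length {len(cds)} != 3 x {len(ungapped)} residues"
            )
        trans = _translate(cds)
        for i, (aa_p, aa_c) in enumerate(zip(ungapped, trans), start=1):
            if aa_c == "*":
                raise ValueError(f"{gid}: internal stop codon at residue {i}")
            if aa_p != aa_c:
                raise ValueError(
                    f"{gid}: translation mismatch at residue {i}: "
                    f"alignment has {aa_p}, CDS encodes {aa_c}"
                )
        codons = iter(cds[i : i + 3] for i in range(0, len(cds), 3))
        out.append("".join(GAP_CODON if aa == "-" else next(codons) for aa in prot))
    return CodonPairAlignment(gene_id_1, gene_id_2, out[0], out[1])


def _codon_usable(c1: str, c2: str) -> bool:
    if "-" in c1 or "-" in c2 or "N" in c1 or "N" in c2:
        return False
    return CODON_TO_AA[c1] != "*" and CODON_TO_AA[c2] != "*"


def classify_fourfold_sites(aln: CodonPairAlignment) -> list[int]:
    """Codon columns usable for 4DTv.

    A column qualifies when both codons are gap- and N-free, share identical
    first two positions, and that two-base prefix is fourfold degenerate
    (any third position encodes the same amino acid).
    """
    sites = []
    for i, c1, c2 in aln.codon_columns():
        if not _codon_usable(c1, c2):
            continue
        if c1[:2] == c2[:2] and c1[:2] in FOURFOLD_PREFIXES:
            sites.append(i)
    return sites


def compute_4dtv(aln: CodonPairAlignment, correct: bool = False) -> FourDTvEstimate:
    """Transversion proportion at fourfold-degenerate third positions.

    With ``correct=True`` the multiple-hit transform ``-0.5 ln(1 - 2 raw)``
    is applied; it is undefined (None) at ``raw >= 0.5``. Raw proportion is
    the primary statistic and the default.
    """
    sites = classify_fourfold_sites(aln)
    if not sites:
        return FourDTvEstimate(0, 0, None, None)
    ntv = 0
    for i in sites:
        a, b = aln.seq1[3 * i + 2], aln.seq2[3 * i + 2]
        if a != b and is_transversion(a, b):
            ntv += 1
    raw = ntv / len(sites)
    corrected: float | None = None
    if correct:
        corrected = -0.5 * math.log(1.0 - 2.0 * raw) if raw < 0.5 else None
    return FourDTvEstimate(len(sites), ntv, raw, corrected)


@lru_cache(maxsize=None)
def synonymous_site_count(codon: str) -> float:
    """NG86 synonymous-site count of a sense codon.

    Each position contributes (number of synonymous single-nucleotide
    changes)/3; changes to stop codons count as nonsynonymous so that
    S + N = 3 per codon.
    """
    aa = CODON_TO_AA[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site counts")
    s = 0
    for pos in range(3):
        for n in NUCLEOTIDES:
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1 :]
            if CODON_TO_AA[alt] == aa:
                s += 1
    return s / 3.0


@lru_cache(maxsize=None)
def pathway_substitution_counts(c1: str, c2: str) -> tuple[float, float]:
    """Equal-weight pathway-averaged (synonymous, nonsynonymous) differences.

    All minimal single-step pathways from *c1* to *c2* are enumerated;
    pathways that pass through a stop codon are excluded. If every pathway
    is blocked by a stop, the average falls back to all pathways.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(exclude_stops: bool) -> list[tuple[int, int]]:
        results = []
        for order in permutations(diffs):
            cur, sd, nd, ok = c1, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if exclude_stops and CODON_TO_AA[nxt] == "*":
                    ok = False
                    break
                if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                results.append((sd, nd))
        return results

    paths = walk(exclude_stops=True) or walk(exclude_stops=False)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None (saturated) when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - p / 0.75) + 0.0


def compute_kaks_ng86(aln: CodonPairAlignment) -> KaKsEstimate:
    """NG86 Ka/Ks with pathway averaging and Jukes–Cantor correction.

    Columns containing gaps, N, or a stop codon in either sequence are
    excluded from all counts. Raises ``ValueError`` when no usable column
    remains (distinct from the saturation-undefined outcome).
    """
    S1 = S2 = Sd = Nd = 0.0
    n_used = 0
    for _, c1, c2 in aln.codon_columns():
        if not _codon_usable(c1, c2):
            continue
        n_used += 1
        S1 += synonymous_site_count(c1)
        S2 += synonymous_site_count(c2)
        sd, nd = pathway_substitution_counts(c1, c2)
        Sd += sd
        Nd += nd
    if n_used == 0:
        raise ValueError(
            f"no usable codon columns in {aln.gene_id_1}/{aln.gene_id_2}"
        )
    S = (S1 + S2) / 2.0
    N = 3.0 * n_used - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    omega = None
    if Ka is not None and Ks is not None and Ks > 0:
        omega = Ka / Ks
    return KaKsEstimate(S, N, Sd, Nd, pS, pN, Ks, Ka, omega, n_used)
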