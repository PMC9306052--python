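"""Synthetic allotetraploid fixtures with planted ground truth.

The generator emulates the study system for every pipeline stage: an
outgroup genome plus a focal allotetraploid whose A and B subgenomes were
created by a WGD/hybridization at a target synonymous divergence, with the
A subgenome constructed closer to the outgroup; a sister focal species at a
recent divergence; collinear gene orders in blocks with occasional
inversions; homology hits with a noise admixture; and lognormal expression
with planted dominant homoeolog pairs and planted DEG effects in a
2-tissue x 4-timepoint x replicated design.

Sequence evolution is a seeded proposal–acceptance scheme: substitution
counts are Poisson on synonymous (and, scaled by omega, nonsynonymous)
sites, and each event is a uniformly proposed single-nucleotide change
accepted when it has the required effect and creates no stop codon.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon import CODON_TO_AA, NUCLEOTIDES, CodonPairAlignment, synonymous_site_count
from .synteny import GeneModel

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimBundle",
    "simulate_codon_pair",
    "simulate_allotetraploid",
    "simulate_expression",
]

SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")

TISSUES = ("leaf", "root")
TIMEPOINTS = ("0", "1", "24", "72")
TREATED_TIMEPOINTS = ("1", "24", "72")


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic allotetraploid.

    Ks targets mirror the zoysiagrass system: a paralog (WGD) peak near
    0.27, a focal–outgroup ortholog peak near 0.48, and a recent sister
    species at 0.03. ``subgenome_asymmetry`` is the extra synonymous
    divergence placed on the B branch so that A is closer to the outgroup.
    """

    seed: int
    n_outgroup_chroms: int = 10
    genes_per_chrom: int = 60
    gene_length_codons: int = 300
    ks_wgd: float = 0.27
    ks_outgroup: float = 0.48
    ks_recent: float = 0.03
    omega_sim: float = 0.2
    retained_duplicate_fraction: float = 0.8
    frac_a_dominant: float = 0.10
    frac_b_dominant: float = 0.15
    planted_deg_fraction: float = 0.05
    deg_effect_log2: float = 2.0
    expr_lognormal_mu: float = 3.0
    expr_lognormal_sigma: float = 1.0
    replicates: int = 3
    noise_cv: float = 0.15
    subgenome_asymmetry: float = 0.08
    inversion_fraction: float = 0.10
    noise_hit_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "retained_duplicate_fraction",
            "frac_a_dominant",
            "frac_b_dominant",
            "planted_deg_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_a_dominant + self.frac_b_dominant > 1:
            raise ValueError("frac_a_dominant + frac_b_dominant must be <= 1")
        for name in ("ks_wgd", "ks_outgroup", "ks_recent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.subgenome_asymmetry > self.ks_wgd and self.ks_wgd > 0:
            raise ValueError("subgenome_asymmetry cannot exceed ks_wgd")


@dataclass
class TruthSet:
    """Ground truth covering every emitted gene, pair and planted effect."""

    chrom_subgenome: dict[str, str] = field(default_factory=dict)
    chrom_partner: dict[str, str] = field(default_factory=dict)
    pairs: list[dict] = field(default_factory=list)
    homoeolog_pairs: list[tuple[str, str]] = field(default_factory=list)
    wgd_triples: list[tuple[str, str, str]] = field(default_factory=list)
    dominance: dict[str, dict] = field(default_factory=dict)  # "geneA|geneB" -> info
    deg: dict[str, dict] = field(default_factory=dict)  # gene -> planted effect
    wgd_ks: float = 0.27

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["homoeolog_pairs"] = [list(p) for p in self.homoeolog_pairs]
        data["wgd_triples"] = [list(t) for t in self.wgd_triples]
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        data = json.loads(Path(path).read_text())
        data["homoeolog_pairs"] = [tuple(p) for p in data["homoeolog_pairs"]]
        data["wgd_triples"] = [tuple(t) for t in data["wgd_triples"]]
        return cls(**data)


def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]


def _total_syn_sites(codons: list[str]) -> float:
    return sum(synonymous_site_count(c) for c in codons)


def _evolve(
    codons: list[str],
    d_syn: float,
    omega: float,
    rng: np.random.Generator,
    max_proposals: int = 10_000_000,
) -> tuple[list[str], int, int]:
    """Evolve a copy of *codons* to an expected synonymous divergence.

    Synonymous substitution events are Poisson with mean ``d_syn * S``;
    nonsynonymous events Poisson with mean ``omega * d_syn * N``. Each event
    is realised by uniform single-nucleotide proposals (codon, position,
    alternative base) accepted when the change has the required effect and
    does not create a stop codon. Returns (sequence, n_syn, n_nonsyn).
    """
    seq = list(codons)
    L = len(seq)
    if L == 0:
        return seq, 0, 0
    S = _total_syn_sites(seq)
    N = 3 * L - S
    n_syn = int(rng.poisson(d_syn * S))
    n_nonsyn = int(rng.poisson(omega * d_syn * N))
    events = ["s"] * n_syn + ["n"] * n_nonsyn
    rng.shuffle(events)
    proposals = 0
    for kind in events:
        while True:
            proposals += 1
            if proposals > max_proposals:
                raise RuntimeError("substitution proposal budget exhausted")
            ci = int(rng.integers(0, L))
            pos = int(rng.integers(0, 3))
            cod = seq[ci]
            alt_bases = [b for b in NUCLEOTIDES if b != cod[pos]]
            nb = alt_bases[int(rng.integers(0, 3))]
            new = cod[:pos] + nb + cod[pos + 1 :]
            if CODON_TO_AA[new] == "*":
                continue
            synonymous = CODON_TO_AA[new] == CODON_TO_AA[cod]
            if (kind == "s") == synonymous:
                seq[ci] = new
                break
    return seq, n_syn, n_nonsyn


def simulate_codon_pair(
    ks_target: float,
    omega_sim: float,
    n_codons: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    gene_id_1: str = "sim1",
    gene_id_2: str = "sim2",
) -> tuple[CodonPairAlignment, dict]:
    """A pair of coding sequences at a target synonymous divergence.

    Both descendants evolve independently from a random sense-codon ancestor
    with half the divergence each. The returned record carries the target
    and the realised substitution-event counts per synonymous site.
    """
    if ks_target < 0:
        raise ValueError("ks_target must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    anc = _random_cds(n_codons, rng)
    s_anc = _total_syn_sites(anc)
    seq1, s1, n1 = _evolve(anc, ks_target / 2.0, omega_sim, rng)
    seq2, s2, n2 = _evolve(anc, ks_target / 2.0, omega_sim, rng)
    record = {
        "ks_target": ks_target,
        "n_syn_events": s1 + s2,
        "n_nonsyn_events": n1 + n2,
        "syn_sites_ancestor": s_anc,
        "realized_syn_per_site": (s1 + s2) / s_anc if s_anc else 0.0,
    }
    aln = CodonPairAlignment(gene_id_1, gene_id_2, "".join(seq1), "".join(seq2))
    return aln, record


def _segment_breakpoints(n_genes: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Cut 0..n_genes into consecutive segments of 10–25 genes.

    Breakpoints are drawn once per ancestral chromosome and shared by both
    subgenome copies, so every planted collinear run stays at (well above)
    the minimum block length even after random fractionation.
    """
    cuts, i = [], 0
    while i < n_genes:
        n = int(rng.integers(10, 26))
        cuts.append((i, min(i + n, n_genes)))
        i += n
    return cuts


def _segment_order(
    gene_ids: list[str],
    segments: list[tuple[int, int]],
    rng: np.random.Generator,
    inversion_fraction: float,
) -> list[tuple[str, str]]:
    """Orient and shuffle pre-cut segments; returns (gene_id, strand).

    ``gene_ids[i]`` may be None (fractionated copy); segment boundaries are
    ancestral indices. A fraction of segments is inverted (order reversed,
    strand flipped) and segment order is shuffled.
    """
    oriented = []
    for lo, hi in segments:
        seg = [g for g in gene_ids[lo:hi] if g is not None]
        if not seg:
            continue
        if rng.random() < inversion_fraction:
            oriented.append([(g, "-") for g in reversed(seg)])
        else:
            oriented.append([(g, "+") for g in seg])
    order = rng.permutation(len(oriented))
    out: list[tuple[str, str]] = []
    for k in order:
        out.extend(oriented[k])
    return out


@dataclass
class SimBundle:
    """Everything `simulate_allotetraploid` produces, with file writers."""

    config: SimConfig
    sequences: dict[str, dict[str, str]]  # genome -> gene_id -> CDS
    annotations: dict[str, list[GeneModel]]  # genome -> gene models
    hits: dict[str, list[tuple]]  # hit-set name -> 12-column rows
    truth: TruthSet
    expression: pd.DataFrame | None = None
    sample_sheet: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from . import io as wio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for genome, seqs in self.sequences.items():
            p = outdir / f"{genome}.cds.fasta"
            wio.write_fasta(seqs, p)
            paths[f"fasta_{genome}"] = p
        for genome, genes in self.annotations.items():
            p = outdir / f"{genome}.genes.gff3"
            wio.write_gff3(genes, p)
            paths[f"gff_{genome}"] = p
        for name, rows in self.hits.items():
            p = outdir / f"hits.{name}.tsv"
            wio.write_hit_rows(rows, p)
            paths[f"hits_{name}"] = p
        p = outdir / "truth.json"
        self.truth.to_json(p)
        paths["truth"] = p
        if self.expression is not None:
            p = outdir / "expression.fpkm.tsv"
            self.expression.to_csv(p, sep="\t", index_label="gene_id")
            paths["expression"] = p
        if self.sample_sheet is not None:
            p = outdir / "samples.tsv"
            self.sample_sheet.to_csv(p, sep="\t", index=False)
            paths["samples"] = p
        return paths


def _hit_row(q: str, s: str, pident: float, length: int, evalue: float, bits: float):
    # 12-column tabular hit format (qseqid sseqid pident length mismatch
    # gapopen qstart qend sstart send evalue bitscore)
    mismatch = int(round(length * (100 - pident) / 100))
    return (q, s, round(pident, 2), length, mismatch, 0, 1, length, 1, length, evalue, bits)


def simulate_allotetraploid(config: SimConfig) -> SimBundle:
    """Generate the outgroup / allotetraploid / sister genome bundle.

    The outgroup genome is duplicated into subgenomes A and B with branch
    lengths chosen so that d(A,B) = ``ks_wgd`` and the B–outgroup distance
    exceeds the A–outgroup distance by ``subgenome_asymmetry`` (A is the
    outgroup-proximal subgenome). A fraction of B copies is deleted at
    random (unbiased fractionation) and a sister focal species diverges from
    the focal genome at ``ks_recent``. Gene orders stay collinear within
    segments, with inversions and segment shuffling; homology hits cover all
    true pairs plus a fraction of random noise hits.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_seq, rng_order, rng_expr, rng_hits = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    del rng_expr  # reserved for simulate_expression (same spawn order)

    n_out = cfg.n_outgroup_chroms
    d_a = cfg.ks_wgd / 2.0 - cfg.subgenome_asymmetry / 2.0
    d_b = cfg.ks_wgd / 2.0 + cfg.subgenome_asymmetry / 2.0
    d_out = max(cfg.ks_outgroup - cfg.ks_wgd / 2.0, 0.0)

    # focal chromosome labels: a shuffled 1..2n numbering hides the subgenome
    perm = rng_order.permutation(2 * n_out)
    chrom_a_label = {k: f"Zj{perm[2 * k] + 1:02d}" for k in range(n_out)}
    chrom_b_label = {k: f"Zj{perm[2 * k + 1] + 1:02d}" for k in range(n_out)}

    truth = TruthSet(wgd_ks=cfg.ks_wgd)
    sequences: dict[str, dict[str, str]] = {"outgroup": {}, "focal": {}, "sister": {}}
    # ancestral-index-aligned gene lists; None marks a fractionated B copy
    order_lists: dict[str, list[str | None]] = {}
    breakpoints: dict[str, list[tuple[int, int]]] = {}

    for k in range(n_out):
        oc = f"Ot{k + 1:02d}"
        ac, bc = chrom_a_label[k], chrom_b_label[k]
        truth.chrom_subgenome[ac] = "A"
        truth.chrom_subgenome[bc] = "B"
        truth.chrom_partner[ac] = oc
        truth.chrom_partner[bc] = oc
        order_lists.setdefault(oc, [])
        order_lists.setdefault(ac, [])
        order_lists.setdefault(bc, [])
        segs = _segment_breakpoints(cfg.genes_per_chrom, rng_order)
        breakpoints[ac] = breakpoints[bc] = segs
        for i in range(cfg.genes_per_chrom):
            anc = _random_cds(cfg.gene_length_codons, rng_seq)
            og_id = f"{oc}g{i + 1:04d}"
            a_id = f"{ac}g{i + 1:04d}"
            b_id = f"{bc}g{i + 1:04d}"
            o_seq, _, _ = _evolve(anc, d_out, cfg.omega_sim, rng_seq)
            a_seq, _, _ = _evolve(anc, d_a, cfg.omega_sim, rng_seq)
            b_seq, _, _ = _evolve(anc, d_b, cfg.omega_sim, rng_seq)
            sequences["outgroup"][og_id] = "".join(o_seq)
            sequences["focal"][a_id] = "".join(a_seq)
            order_lists[oc].append(og_id)
            order_lists[ac].append(a_id)
            b_retained = bool(rng_order.random() < cfg.retained_duplicate_fraction)
            truth.pairs.append(
                {
                    "gene_1": a_id,
                    "gene_2": og_id,
                    "cls": "ortholog_A_outgroup",
                    "target_ks": cfg.ks_outgroup - cfg.subgenome_asymmetry / 2.0,
                }
            )
            if b_retained:
                sequences["focal"][b_id] = "".join(b_seq)
                order_lists[bc].append(b_id)
                truth.homoeolog_pairs.append((a_id, b_id))
                truth.wgd_triples.append((a_id, b_id, og_id))
                truth.pairs.append(
                    {
                        "gene_1": a_id,
                        "gene_2": b_id,
                        "cls": "wgd_paralog",
                        "target_ks": cfg.ks_wgd,
                    }
                )
                truth.pairs.append(
                    {
                        "gene_1": b_id,
                        "gene_2": og_id,
                        "cls": "ortholog_B_outgroup",
                        "target_ks": cfg.ks_outgroup + cfg.subgenome_asymmetry / 2.0,
                    }
                )
            else:
                order_lists[bc].append(None)
            # sister species copy of every retained focal gene
            for fid, fseq in ((a_id, a_seq), (b_id, b_seq) if b_retained else (None, None)):
                if fid is None:
                    continue
                sid = "Zs" + fid[2:]
                s_seq, _, _ = _evolve(fseq, cfg.ks_recent, cfg.omega_sim, rng_seq)
                sequences["sister"][sid] = "".join(s_seq)
                truth.pairs.append(
                    {
                        "gene_1": fid,
                        "gene_2": sid,
                        "cls": "ortholog_sister",
                        "target_ks": cfg.ks_recent,
                    }
                )

    # gene orders: outgroup keeps ancestral order; focal chromosomes are
    # segmented, partially inverted and shuffled; sister mirrors focal
    annotations: dict[str, list[GeneModel]] = {"outgroup": [], "focal": [], "sister": []}
    gene_len = 3 * cfg.gene_length_codons
    spacing = gene_len + 1000
    for oc in sorted(c for c in order_lists if c.startswith("Ot")):
        for r, gid in enumerate(order_lists[oc]):
            annotations["outgroup"].append(
                GeneModel(gid, oc, r * spacing, r * spacing + gene_len, "+")
            )
    for fc in sorted(c for c in order_lists if c.startswith("Zj")):
        placed = _segment_order(
            order_lists[fc], breakpoints[fc], rng_order, cfg.inversion_fraction
        )
        for r, (gid, strand) in enumerate(placed):
            annotations["focal"].append(
                GeneModel(gid, fc, r * spacing, r * spacing + gene_len, strand)
            )
            sid = "Zs" + gid[2:]
            annotations["sister"].append(
                GeneModel(sid, "Zs" + fc[2:], r * spacing, r * spacing + gene_len, strand)
            )

    # homology hits: true pairs plus uniform random noise pairs
    hits: dict[str, list[tuple]] = {
        "focal_self": [],
        "focal_outgroup": [],
        "focal_sister": [],
    }
    ident = {
        "wgd_paralog": 88.0,
        "ortholog_A_outgroup": 82.0,
        "ortholog_B_outgroup": 80.0,
        "ortholog_sister": 99.0,
    }
    setname = {
        "wgd_paralog": "focal_self",
        "ortholog_A_outgroup": "focal_outgroup",
        "ortholog_B_outgroup": "focal_outgroup",
        "ortholog_sister": "focal_sister",
    }
    for p in truth.pairs:
        hits[setname[p["cls"]]].append(
            _hit_row(p["gene_1"], p["gene_2"], ident[p["cls"]], gene_len, 1e-180, 500.0)
        )
    focal_ids = sorted(sequences["focal"])
    out_ids = sorted(sequences["outgroup"])
    sister_ids = sorted(sequences["sister"])
    pools = {
        "focal_self": (focal_ids, focal_ids),
        "focal_outgroup": (focal_ids, out_ids),
        "focal_sister": (focal_ids, sister_ids),
    }
    for name, rows in hits.items():
        qpool, spool = pools[name]
        n_noise = int(round(cfg.noise_hit_fraction * len(rows)))
        for _ in range(n_noise):
            q = qpool[int(rng_hits.integers(0, len(qpool)))]
            s = spool[int(rng_hits.integers(0, len(spool)))]
            if q == s:
                continue
            rows.append(_hit_row(q, s, 45.0, gene_len // 3, 1e-15, 60.0))

    return SimBundle(cfg, sequences, annotations, hits, truth)


def simulate_expression(
    truth: TruthSet,
    config: SimConfig,
    focal_gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM matrix and sample sheet with planted dominance and DEG effects.

    Homoeolog pairs share a lognormal baseline so unplanted pairs are
    unbiased; planted dominant pairs multiply the dominant member by
    ``2**u`` with u uniform in [1.5, 3]; planted DEG genes shift by
    ``deg_effect_log2`` (random sign) at the treated timepoints of one
    tissue. Replicate noise is multiplicative lognormal with the configured
    coefficient of variation. Planted flags are written into *truth*.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(4)[2])  # the "expression" stream

    pairs = list(truth.homoeolog_pairs)
    paired_genes = {g for p in pairs for g in p}
    if focal_gene_ids is None:
        focal_gene_ids = sorted(paired_genes)
    genes = sorted(set(focal_gene_ids) | paired_genes)

    baseline: dict[str, float] = {}
    for a, b in pairs:
        base = float(rng.lognormal(cfg.expr_lognormal_mu, cfg.expr_lognormal_sigma))
        baseline[a] = baseline[b] = base
    for g in genes:
        if g not in baseline:
            baseline[g] = float(
                rng.lognormal(cfg.expr_lognormal_mu, cfg.expr_lognormal_sigma)
            )

    # planted dominance
    n_pairs = len(pairs)
    n_a = int(round(cfg.frac_a_dominant * n_pairs))
    n_b = int(round(cfg.frac_b_dominant * n_pairs))
    chosen = rng.choice(n_pairs, size=n_a + n_b, replace=False) if n_pairs else []
    dom_factor: dict[str, float] = {}
    truth.dominance = {}
    for idx, pair_i in enumerate(chosen):
        a, b = pairs[pair_i]
        direction = "A" if idx < n_a else "B"
        u = float(rng.uniform(1.5, 3.0))
        dom_factor[a if direction == "A" else b] = 2.0**u
        truth.dominance[f"{a}|{b}"] = {"direction": direction, "log2_ratio": u}
    for a, b in pairs:
        truth.dominance.setdefault(f"{a}|{b}", {"direction": None, "log2_ratio": 0.0})

    # planted DEGs
    n_deg = int(round(cfg.planted_deg_fraction * len(genes)))
    deg_genes = rng.choice(len(genes), size=n_deg, replace=False) if n_deg else []
    truth.deg = {}
    for gi in deg_genes:
        g = genes[gi]
        tissue = TISSUES[int(rng.integers(0, len(TISSUES)))]
        sign = 1 if rng.random() < 0.5 else -1
        truth.deg[g] = {
            "tissue": tissue,
            "sign": sign,
            "effect_log2": cfg.deg_effect_log2,
        }

    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))
    samples = []
    for tissue in TISSUES:
        for tp in TIMEPOINTS:
            for rep in range(1, cfg.replicates + 1):
                samples.append(
                    {
                        "sample": f"{tissue}_{tp}h_r{rep}",
                        "tissue": tissue,
                        "timepoint": tp,
                        "replicate": rep,
                    }
                )
    sheet = pd.DataFrame(samples)

    values = np.empty((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        expected = np.empty(len(samples))
        for si, s in enumerate(samples):
            v = baseline[g] * dom_factor.get(g, 1.0)
            planted = truth.deg.get(g)
            if (
                planted
                and s["tissue"] == planted["tissue"]
                and s["timepoint"] in TREATED_TIMEPOINTS
            ):
                v *= 2.0 ** (planted["sign"] * planted["effect_log2"])
            expected[si] = v
        if sigma > 0:
            noise = rng.lognormal(-(sigma**2) / 2.0, sigma, size=len(samples))
        else:
            noise = np.ones(len(samples))
        values[gi] = expected * noise
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sheet["sample"])
    return matrix, sheet
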