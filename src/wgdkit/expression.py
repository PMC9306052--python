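"""Homoeolog expression bias, DEG calling, and divergence classification.

HEB (homoeolog expression bias) is ``log2((A + c) / (B + c))`` for an A/B
syntenic gene pair; a pair is dominant toward a subgenome when the ratio
reaches 2-fold (HEB >= 1 toward A, <= -1 toward B; boundaries inclusive).
DEGs follow the fold-change rule ``p < 0.05 and |log2FC| >= 1`` with
p-values from Welch's t-test on log-transformed FPKM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BiasConfig",
    "HomoeologRecord",
    "compute_heb",
    "classify_dominance",
    "heb_summary",
    "call_degs",
    "subgenome_deg_chisq",
    "classify_paralog_pair_divergence",
    "hypergeom_enrichment",
]


@dataclass
class BiasConfig:
    dominance_ratio: float = 2.0
    pseudocount: float = 0.1  # FPKM added to both members
    expression_floor: float = 1.0  # max of pair must reach this FPKM
    p_threshold: float = 0.05
    fc_threshold: float = 1.0  # |log2 fold change|

    def __post_init__(self) -> None:
        if self.dominance_ratio <= 1:
            raise ValueError("dominance_ratio must exceed 1")
        if self.pseudocount < 0 or self.expression_floor < 0:
            raise ValueError("pseudocount and expression_floor must be >= 0")


@dataclass
class HomoeologRecord:
    """An A/B syntenic gene pair with per-sample HEB and dominance calls."""

    gene_a: str
    gene_b: str
    chrom_a: str = ""
    chrom_b: str = ""
    heb: dict[str, float | None] = field(default_factory=dict)
    dominance: dict[str, str] = field(default_factory=dict)


def compute_heb(expr_a: float, expr_b: float, config: BiasConfig | None = None):
    """HEB of one pair in one sample; None when the pair is untestable.

    Untestable means neither member reaches ``expression_floor`` FPKM.
    Positive values indicate bias toward the A subgenome.
    """
    config = config or BiasConfig()
    if expr_a < 0 or expr_b < 0:
        raise ValueError("FPKM values must be non-negative")
    if max(expr_a, expr_b) < config.expression_floor:
        return None
    num, den = expr_a + config.pseudocount, expr_b + config.pseudocount
    if den == 0:
        return math.inf if num > 0 else 0.0
    if num == 0:
        return -math.inf
    # difference of logs keeps heb(a, b) == -heb(b, a) exactly
    return math.log2(num) - math.log2(den)


def classify_dominance(heb: float, config: BiasConfig | None = None) -> str:
    """A_dominant / B_dominant / neutral; ratio boundaries are inclusive."""
    config = config or BiasConfig()
    cut = math.log2(config.dominance_ratio)
    if heb >= cut:
        return "A_dominant"
    if heb <= -cut:
        return "B_dominant"
    return "neutral"


def heb_summary(records: list[HomoeologRecord]) -> dict:
    """Genome-wide HEB tallies.

    Reports the number of pairs dominant in at least one sample, the fraction
    of those whose majority-sample direction is B (ties excluded and counted
    separately), event-level tallies, per-chromosome-pair direction counts,
    and per-sample dominant totals.
    """
    n_biased = 0
    majority = {"A": 0, "B": 0, "tie": 0}
    events = {"A": 0, "B": 0}
    per_chrom: dict[tuple[str, str], dict[str, int]] = {}
    per_sample: dict[str, dict[str, int]] = {}
    for rec in records:
        calls = [c for c in rec.dominance.values() if c.endswith("_dominant")]
        for sample, call in rec.dominance.items():
            if call.endswith("_dominant"):
                events[call[0]] += 1
                per_sample.setdefault(sample, {"A": 0, "B": 0})[call[0]] += 1
        if not calls:
            continue
        n_biased += 1
        n_a = sum(1 for c in calls if c == "A_dominant")
        n_b = len(calls) - n_a
        direction = "A" if n_a > n_b else "B" if n_b > n_a else "tie"
        majority[direction] += 1
        key = (rec.chrom_a, rec.chrom_b)
        per_chrom.setdefault(key, {"A": 0, "B": 0, "tie": 0})[direction] += 1
    decided = majority["A"] + majority["B"]
    return {
        "n_pairs_biased_any_sample": n_biased,
        "n_pairs_majority_a": majority["A"],
        "n_pairs_majority_b": majority["B"],
        "n_pairs_tied": majority["tie"],
        "fraction_b_of_biased": majority["B"] / decided if decided else float("nan"),
        "n_events_a": events["A"],
        "n_events_b": events["B"],
        "fraction_b_of_events": (
            events["B"] / (events["A"] + events["B"])
            if events["A"] + events["B"]
            else float("nan")
        ),
        "per_chromosome_pair": {
            f"{a}|{b}": counts for (a, b), counts in sorted(per_chrom.items())
        },
        "per_sample": dict(sorted(per_sample.items())),
    }


def _welch_p(treated_log: np.ndarray, control_log: np.ndarray) -> float:
    vt, vc = treated_log.var(ddof=1), control_log.var(ddof=1)
    if vt == 0 and vc == 0:
        return 1.0 if np.isclose(treated_log.mean(), control_log.mean()) else 0.0
    return float(
        stats.ttest_ind(treated_log, control_log, equal_var=False).pvalue
    )


def call_degs(
    matrix: pd.DataFrame,
    treated_samples: list[str],
    control_samples: list[str],
    contrast_id: str = "",
    config: BiasConfig | None = None,
) -> pd.DataFrame:
    """Differential expression for one contrast (treated vs control).

    *matrix* is genes x samples (FPKM). log2FC uses replicate-mean FPKM with
    the configured pseudocount; p-values come from Welch's t-test on
    ``log2(FPKM + pseudocount)``. A gene is a DEG when
    ``p < p_threshold`` and ``|log2FC| >= fc_threshold``.
    """
    config = config or BiasConfig()
    if len(treated_samples) < 2 or len(control_samples) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if (matrix[treated_samples + control_samples].values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    pc = config.pseudocount
    t = matrix[treated_samples].to_numpy(dtype=float)
    c = matrix[control_samples].to_numpy(dtype=float)
    log2fc = np.log2(t.mean(axis=1) + pc) - np.log2(c.mean(axis=1) + pc)
    tl, cl = np.log2(t + pc), np.log2(c + pc)
    pvals = np.array([_welch_p(tl[i], cl[i]) for i in range(len(matrix))])
    is_deg = (pvals < config.p_threshold) & (np.abs(log2fc) >= config.fc_threshold)
    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "contrast": contrast_id,
            "log2fc": log2fc,
            "pvalue": pvals,
            "is_deg": is_deg,
        }
    ).set_index("gene_id")


def subgenome_deg_chisq(count_a: int, count_b: int) -> tuple[float, float]:
    """1-df goodness-of-fit of A vs B DEG counts against equal expectation.

    For the balanced null, ``chi2 = sum (obs - exp)^2 / exp`` with
    ``exp = (count_a + count_b) / 2``; returns (chi2, upper-tail p).
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    total = count_a + count_b
    if total == 0:
        raise ValueError("need at least one DEG")
    exp = total / 2.0
    chi2 = (count_a - exp) ** 2 / exp + (count_b - exp) ** 2 / exp
    return chi2, float(stats.chi2.sf(chi2, df=1))


def classify_paralog_pair_divergence(
    pairs: list[tuple[str, str]],
    deg_sets: dict[str, set[str]],
    universe: set[str],
) -> tuple[dict[tuple[str, str], int], dict[int, int]]:
    """Count DEG members per WGD-paralog pair (0, 1 or 2).

    A gene counts as a DEG when it is differentially expressed in *any*
    contrast of *deg_sets*. Pair members must belong to *universe*.
    """
    any_deg = set().union(*deg_sets.values()) if deg_sets else set()
    classes: dict[tuple[str, str], int] = {}
    counts = {0: 0, 1: 0, 2: 0}
    for g1, g2 in pairs:
        for g in (g1, g2):
            if g not in universe:
                raise ValueError(f"gene not in DEG universe: {g!r}")
        k = int(g1 in any_deg) + int(g2 in any_deg)
        classes[(g1, g2)] = k
        counts[k] += 1
    return classes, counts


def hypergeom_enrichment(
    study_set: set[str],
    population: set[str],
    annotations: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    Terms are restricted to the population; p-values are BH-adjusted across
    terms and the table is sorted by raw p.
    """
    if not study_set <= population:
        raise ValueError("study set must be a subset of the population")
    M, N = len(population), len(study_set)
    rows = []
    for term in sorted(annotations):
        term_genes = annotations[term] & population
        n = len(term_genes)
        k = len(term_genes & study_set)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {"term": term, "k_study": k, "n_term": n, "n_study": N, "n_pop": M, "pvalue": min(p, 1.0)}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr_bh"] = multipletests(df["pvalue"], method="fdr_bh")[1]
        df = df.sort_values(["pvalue", "term"], kind="stable").reset_index(drop=True)
    else:
        df["fdr_bh"] = []
    return df
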