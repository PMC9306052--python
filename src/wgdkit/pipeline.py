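"""End-to-end orchestration: simulate → Ka/Ks → synteny → dating → phasing
→ expression bias, with file-based stage boundaries and a JSON run report.

Every stage reads and writes plain TSV/FASTA/JSON under the output
directory, so any stage can be re-run or replaced independently. The run
report collects the headline quantities (Ks modes and ages, the phasing
table, HEB and DEG tallies, paralog divergence classes) together with a
config fingerprint; each number in it is recomputed from stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .codon import CodonPairAlignment, compute_4dtv, compute_kaks_ng86
from .dating import DistributionConfig, collect_ks_values, date_event, detect_peaks, summarize_wgd
from .expression import (
    BiasConfig,
    HomoeologRecord,
    call_degs,
    classify_dominance,
    classify_paralog_pair_divergence,
    compute_heb,
    heb_summary,
    subgenome_deg_chisq,
)
from .phasing import assign_subgenomes, build_nj_tree, chromosome_distances
from .simulate import SimConfig, simulate_allotetraploid, simulate_expression
from .synteny import (
    SyntenyParams,
    build_gene_ranks,
    chain_collinear_blocks,
    collapse_tandem_hits,
    extract_homoeolog_pairs,
    extract_wgd_paralog_pairs,
    filter_hits,
)

logger = logging.getLogger("wgdkit")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 1
    simulate: dict | None = None  # SimConfig overrides; None = file inputs
    inputs: dict = field(default_factory=dict)
    synteny: dict = field(default_factory=dict)
    distribution: dict = field(default_factory=dict)
    bias: dict = field(default_factory=dict)
    lambda_rate: float = 6.5e-9

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sim_config(self) -> SimConfig:
        overrides = dict(self.simulate or {})
        overrides.setdefault("seed", self.seed)
        return SimConfig(**overrides)

    def synteny_params(self) -> SyntenyParams:
        return SyntenyParams(**self.synteny)

    def distribution_config(self) -> DistributionConfig:
        return DistributionConfig(**self.distribution)

    def bias_config(self) -> BiasConfig:
        return BiasConfig(**self.bias)


def validate_inputs(config: PipelineConfig) -> dict:
    """Cross-check the declared input files; returns {passed, issues}."""
    issues: list[str] = []
    if config.simulate is not None:
        try:
            config.sim_config()
        except (TypeError, ValueError) as exc:
            issues.append(f"simulate block invalid: {exc}")
        return {"passed": not issues, "issues": issues}

    inputs = config.inputs
    required = ["fasta_focal", "gff_focal", "hits_focal_self"]
    for key in required:
        if key not in inputs:
            issues.append(f"missing required input: {key}")
    paths = {k: Path(v) for k, v in inputs.items()}
    for k, p in paths.items():
        if not p.exists():
            issues.append(f"{k}: file not found: {p}")
    if issues:
        return {"passed": False, "issues": issues}

    for genome in ("focal", "outgroup", "sister"):
        fk, gk = f"fasta_{genome}", f"gff_{genome}"
        if fk in paths and gk in paths:
            seqs = wio.read_fasta(paths[fk])
            genes = wio.read_gff3(paths[gk])
            for g in genes:
                if g.gene_id not in seqs:
                    issues.append(f"{gk}: gene {g.gene_id} absent from {fk}")
            gene_ids = {g.gene_id for g in genes}
            for sid in seqs:
                if sid not in gene_ids:
                    issues.append(f"{fk}: sequence {sid} absent from {gk}")
            for g in genes:
                if len(seqs.get(g.gene_id, "")) % 3 != 0:
                    issues.append(f"{fk}: {g.gene_id} length not divisible by 3")
    if "expression" in paths:
        matrix = wio.read_expression(paths["expression"])
        if "samples" not in paths:
            issues.append("expression given without a sample sheet")
        else:
            try:
                sheet = wio.read_sample_sheet(paths["samples"])
            except ValueError as exc:
                issues.append(str(exc))
            else:
                for s in sheet["sample"]:
                    if s not in matrix.columns:
                        issues.append(f"sample sheet sample {s} absent from matrix")
                reps = sheet.groupby(["tissue", "timepoint"]).size()
                for key, n in reps.items():
                    if n < 2:
                        issues.append(f"group {key} has {n} replicate(s); need >= 2")
    return {"passed": not issues, "issues": issues}


def _hits_from_rows(rows):
    from .synteny import HomologyHit

    return [HomologyHit(r[0], r[1], float(r[11]), float(r[10]), float(r[2])) for r in rows]


def _kaks_for_pairs(pairs, sequences, skipped) -> list[dict]:
    rows = []
    for g1, g2 in pairs:
        s1, s2 = sequences.get(g1), sequences.get(g2)
        if s1 is None or s2 is None or len(s1) != len(s2) or len(s1) % 3:
            skipped.append((g1, g2))
            continue
        aln = CodonPairAlignment(g1, g2, s1, s2)
        try:
            est = compute_kaks_ng86(aln)
        except ValueError:
            skipped.append((g1, g2))
            continue
        fd = compute_4dtv(aln, correct=True)
        rows.append(
            {
                "gene1": g1,
                "gene2": g2,
                "n_codons_used": est.n_codons_used,
                "S": est.S,
                "N": est.N,
                "Sd": est.Sd,
                "Nd": est.Nd,
                "Ks": est.Ks,
                "Ka": est.Ka,
                "omega": est.omega,
                "n_4d_sites": fd.n_4d_sites,
                "raw_4dtv": fd.raw_4dtv,
                "corrected_4dtv": fd.corrected_4dtv,
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written to disk)."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config_fingerprint": config.fingerprint(),
        "stages": {},
    }

    validation = validate_inputs(config)
    if not validation["passed"]:
        raise ValueError(f"input validation failed: {validation['issues']}")

    # ---- stage: synthetic data (optional) --------------------------------
    truth = None
    if config.simulate is not None:
        t0 = time.time()
        sim_cfg = config.sim_config()
        bundle = simulate_allotetraploid(sim_cfg)
        matrix, sheet = simulate_expression(
            bundle.truth, sim_cfg, sorted(bundle.sequences["focal"])
        )
        bundle.expression, bundle.sample_sheet = matrix, sheet
        fixture_dir = outdir / "fixture"
        paths = bundle.write(fixture_dir)
        truth = bundle.truth
        sequences = {g: dict(s) for g, s in bundle.sequences.items()}
        annotations = bundle.annotations
        hit_rows = bundle.hits
        logger.info(
            "stage=simulate genes=%d wall=%.1fs",
            sum(len(s) for s in sequences.values()),
            time.time() - t0,
        )
        report["stages"]["simulate"] = {
            "n_genes": {g: len(s) for g, s in sequences.items()},
            "n_homoeolog_pairs_planted": len(truth.homoeolog_pairs),
            "fixture_dir": str(fixture_dir),
        }
    else:
        inputs = config.inputs
        sequences, annotations, hit_rows = {}, {}, {}
        for genome in ("focal", "outgroup", "sister"):
            if f"fasta_{genome}" in inputs:
                sequences[genome] = wio.read_fasta(inputs[f"fasta_{genome}"])
                annotations[genome] = wio.read_gff3(inputs[f"gff_{genome}"])
        for name in ("focal_self", "focal_outgroup", "focal_sister"):
            key = f"hits_{name}"
            if key in inputs:
                hits = wio.read_hits(inputs[key])
                hit_rows[name] = [
                    (h.query_id, h.subject_id, h.identity_pct, 0, 0, 0, 0, 0, 0, 0, h.evalue, h.bitscore)
                    for h in hits
                ]
        matrix = wio.read_expression(inputs["expression"]) if "expression" in inputs else None
        sheet = wio.read_sample_sheet(inputs["samples"]) if "samples" in inputs else None

    all_seqs: dict[str, str] = {}
    for s in sequences.values():
        all_seqs.update(s)

    # ---- stage: synteny ---------------------------------------------------
    t0 = time.time()
    params = config.synteny_params()
    ranks = {g: build_gene_ranks(a) for g, a in annotations.items()}
    blocks: dict[str, list] = {}
    for name, rows in hit_rows.items():
        hits = filter_hits(_hits_from_rows(rows))
        if name == "focal_self":
            hits = collapse_tandem_hits(hits, ranks["focal"])
            blocks[name] = chain_collinear_blocks(
                hits, ranks["focal"], None, params, within=True
            )
        else:
            other = "outgroup" if name == "focal_outgroup" else "sister"
            if other not in ranks:
                continue
            blocks[name] = chain_collinear_blocks(hits, ranks["focal"], ranks[other], params)
    block_rows, anchor_rows = [], []
    for name, blks in blocks.items():
        for b in blks:
            block_rows.append(
                {
                    "set": name,
                    "block_id": b.block_id,
                    "chrom_a": b.chrom_a,
                    "chrom_b": b.chrom_b,
                    "orientation": b.orientation,
                    "n_anchors": len(b.anchors),
                    "score": b.score,
                }
            )
            for ga, gb in b.anchors:
                anchor_rows.append(
                    {"set": name, "block_id": b.block_id, "gene_a": ga, "gene_b": gb}
                )
    pd.DataFrame(block_rows).to_csv(outdir / "blocks.tsv", sep="\t", index=False)
    pd.DataFrame(anchor_rows).to_csv(outdir / "anchors.tsv", sep="\t", index=False)
    logger.info(
        "stage=synteny blocks=%d anchors=%d wall=%.1fs",
        len(block_rows),
        len(anchor_rows),
        time.time() - t0,
    )
    report["stages"]["synteny"] = {
        "n_blocks": {name: len(b) for name, b in blocks.items()},
        "n_anchors": {
            name: sum(len(b.anchors) for b in blks) for name, blks in blocks.items()
        },
    }

    # ---- stage: codon statistics on anchor pairs -------------------------
    t0 = time.time()
    kaks_tables: dict[str, pd.DataFrame] = {}
    skipped: list = []
    for name, blks in blocks.items():
        pairs = [p for b in blks for p in b.anchors]
        rows = _kaks_for_pairs(pairs, all_seqs, skipped)
        df = wio.kaks_table(rows)
        kaks_tables[name] = df
        wio.write_kaks_table(df, outdir / f"kaks.{name}.tsv")
    logger.info("stage=codonstats pairs=%d skipped=%d wall=%.1fs",
                sum(len(t) for t in kaks_tables.values()), len(skipped), time.time() - t0)
    report["stages"]["codonstats"] = {
        "n_pairs": {name: int(len(t)) for name, t in kaks_tables.items()},
        "n_skipped": len(skipped),
    }

    # ---- stage: WGD dating ------------------------------------------------
    t0 = time.time()
    dist_cfg = config.distribution_config()
    peaksets = {}
    filter_counts = {}
    kind_by_set = {
        "focal_self": ("paralogs_within_focal", "within"),
        "focal_outgroup": ("orthologs_focal_outgroup", "between"),
        "focal_sister": ("orthologs_focal_sister", "between"),
    }
    for name, df in kaks_tables.items():
        comp, kind = kind_by_set[name]
        ks_series = [None if pd.isna(v) else float(v) for v in df["Ks"]]
        try:
            values, dropped = collect_ks_values(ks_series, dist_cfg)
        except ValueError as exc:
            filter_counts[comp] = {"error": str(exc)}
            continue
        filter_counts[comp] = dropped
        peaksets[comp] = (detect_peaks(values, dist_cfg, config.lambda_rate), kind)
    events = summarize_wgd(peaksets)
    events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    # internal consistency: every age equals the dating formula on its mode
    for row in events.itertuples():
        assert abs(row.age_mya - date_event(row.mode_ks, row.lambda_rate)) < 1e-9
    logger.info("stage=dating events=%d wall=%.1fs", len(events), time.time() - t0)
    report["stages"]["dating"] = {
        "lambda_rate": config.lambda_rate,
        "filter_counts": filter_counts,
        "events": events.to_dict(orient="records"),
        "n_wgd_candidates": int((events["label"] == "WGD-candidate").sum()),
    }

    # ---- stage: subgenome phasing ----------------------------------------
    t0 = time.time()
    phasing_report = {}
    assignment = None
    if "focal_outgroup" in kaks_tables and "outgroup" in annotations:
        chrom_of = {m.gene_id: m.chromosome for a in annotations.values() for m in a}
        for gid in all_seqs:
            chrom_of.setdefault(gid, "")
        groups: dict[tuple[str, str], list] = {}
        for row in kaks_tables["focal_outgroup"].itertuples():
            key = (chrom_of[row.gene1], chrom_of[row.gene2])
            groups.setdefault(key, []).append(None if pd.isna(row.Ks) else row.Ks)
        within_groups: dict[tuple[str, str], list] = {}
        for row in kaks_tables.get("focal_self", pd.DataFrame()).itertuples():
            key = tuple(sorted((chrom_of[row.gene1], chrom_of[row.gene2])))
            within_groups.setdefault(key, []).append(None if pd.isna(row.Ks) else row.Ks)
        matrix_d = chromosome_distances(groups)
        outgroup_chroms = {c for c in matrix_d.labels if c in {m.chromosome for m in annotations["outgroup"]}}
        sharing = {
            frozenset(k): float(np.nansum([v for v in vals if v is not None]))
            for k, vals in within_groups.items()
            if len(set(k)) == 2
        }
        result = assign_subgenomes(matrix_d, outgroup_chroms, block_sharing=sharing)
        result.to_frame().to_csv(outdir / "phasing.tsv", sep="\t", index=False)
        assignment = result.assignment
        # per-trio NJ trees (focal pair + outgroup partner)
        trees = []
        from .phasing import ChromosomeDistanceMatrix

        by_partner: dict[str, list[str]] = {}
        for f, og in result.partner.items():
            by_partner.setdefault(og, []).append(f)
        for og in sorted(by_partner):
            pair = sorted(by_partner[og])
            if len(pair) != 2:
                continue
            f1, f2 = pair
            d12 = within_groups.get((f1, f2)) or within_groups.get((f2, f1))
            if not d12:
                continue
            d12 = float(np.mean([v for v in d12 if v is not None]))
            d1o, d2o = matrix_d.get(f1, og), matrix_d.get(f2, og)
            if np.isnan(d1o) or np.isnan(d2o):
                continue
            trio = ChromosomeDistanceMatrix(
                [f1, f2, og],
                np.array([[0, d12, d1o], [d12, 0, d2o], [d1o, d2o, 0]]),
            )
            trees.append(build_nj_tree(trio))
        (outdir / "chromosome_trees.nwk").write_text("\n".join(trees) + "\n")
        phasing_report = {
            "assignment": dict(sorted(assignment.items())),
            "partner": dict(sorted(result.partner.items())),
            "n_a": sum(1 for v in assignment.values() if v == "A"),
            "n_b": sum(1 for v in assignment.values() if v == "B"),
            "n_low_confidence": len(result.low_confidence),
            "n_trees": len(trees),
        }
    logger.info("stage=phasing wall=%.1fs", time.time() - t0)
    report["stages"]["phasing"] = phasing_report

    # ---- stage: expression bias ------------------------------------------
    t0 = time.time()
    expr_report = {}
    if matrix is not None and sheet is not None and assignment is not None:
        bias_cfg = config.bias_config()
        chrom_of = {m.gene_id: m.chromosome for m in annotations["focal"]}
        pairs = extract_homoeolog_pairs(blocks.get("focal_self", []), assignment)
        pairs = [
            p for p in pairs if p[0] in matrix.index and p[1] in matrix.index
        ]
        # replicate-mean FPKM per (tissue, timepoint) biological sample
        group_cols = sheet.groupby(["tissue", "timepoint"])["sample"].apply(list)
        sample_means = {
            f"{tissue}_{tp}h": matrix[cols].mean(axis=1)
            for (tissue, tp), cols in group_cols.items()
        }
        records = []
        heb_rows = []
        for ga, gb in pairs:
            rec = HomoeologRecord(ga, gb, chrom_of.get(ga, ""), chrom_of.get(gb, ""))
            for sname, means in sample_means.items():
                heb = compute_heb(float(means[ga]), float(means[gb]), bias_cfg)
                rec.heb[sname] = heb
                call = "untestable" if heb is None else classify_dominance(heb, bias_cfg)
                rec.dominance[sname] = call
                heb_rows.append(
                    {"gene_a": ga, "gene_b": gb, "sample": sname,
                     "heb": heb, "dominance": call}
                )
            records.append(rec)
        pd.DataFrame(heb_rows).to_csv(
            outdir / "heb.tsv", sep="\t", index=False, na_rep="NA"
        )
        summary = heb_summary(records)

        # DEG calling: each tissue x treated timepoint vs 0 h
        deg_frames = []
        deg_sets: dict[str, set[str]] = {}
        for tissue in sorted(sheet["tissue"].unique()):
            control = group_cols.get((tissue, "0"), [])
            for tp in sorted(sheet["timepoint"].unique(), key=str):
                if tp == "0":
                    continue
                treated = group_cols.get((tissue, tp), [])
                if len(treated) < 2 or len(control) < 2:
                    continue
                cid = f"{tissue}_{tp}h_vs_0h"
                df = call_degs(matrix, treated, control, cid, bias_cfg)
                deg_frames.append(df.reset_index())
                deg_sets[cid] = set(df.index[df["is_deg"]])
        degs = pd.concat(deg_frames, ignore_index=True)
        degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
        deg_counts = {cid: len(s) for cid, s in deg_sets.items()}

        # subgenome balance of DEGs
        any_deg = set().union(*deg_sets.values()) if deg_sets else set()
        count_a = sum(1 for g in any_deg if assignment.get(chrom_of.get(g)) == "A")
        count_b = sum(1 for g in any_deg if assignment.get(chrom_of.get(g)) == "B")
        if count_a + count_b:
            chi2, pval = subgenome_deg_chisq(count_a, count_b)
        else:
            chi2, pval = float("nan"), float("nan")

        # WGD paralog-pair divergence classes
        triples = extract_wgd_paralog_pairs(
            blocks.get("focal_self", []), blocks.get("focal_outgroup", [])
        )
        universe = set(matrix.index)
        wgd_pairs = [
            (c1, c2) for c1, c2, _ in triples if c1 in universe and c2 in universe
        ]
        classes, class_counts = classify_paralog_pair_divergence(
            wgd_pairs, deg_sets, universe
        )
        pd.DataFrame(
            [{"copy1": a, "copy2": b, "n_deg_members": k} for (a, b), k in classes.items()]
        ).to_csv(outdir / "paralog_classes.tsv", sep="\t", index=False)

        expr_report = {
            "n_pairs_tested": len(records),
            "heb_summary": summary,
            "deg_counts": deg_counts,
            "n_deg_any_contrast": len(any_deg),
            "subgenome_deg_counts": {"A": count_a, "B": count_b},
            "subgenome_chisq": {"chi2": chi2, "pvalue": pval},
            "paralog_class_counts": {str(k): v for k, v in class_counts.items()},
            "n_wgd_pairs": len(wgd_pairs),
        }
    logger.info("stage=expression wall=%.1fs", time.time() - t0)
    report["stages"]["expression"] = expr_report

    report["wall_seconds"] = round(time.time() - t_start, 2)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
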