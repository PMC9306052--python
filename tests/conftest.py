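"""Shared fixtures: the default synthetic allotetraploid and derived objects.

The heavy objects (genome bundle, synteny blocks, pipeline report) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import pytest

from wgdkit import synteny
from wgdkit.pipeline import PipelineConfig, run_pipeline
from wgdkit.simulate import SimConfig, simulate_allotetraploid, simulate_expression

#: seed for the study-condition fixture used across the suite
FIXTURE_SEED = 1


def hits_from_rows(rows):
    return [
        synteny.HomologyHit(r[0], r[1], float(r[11]), float(r[10]), float(r[2]))
        for r in rows
    ]


@pytest.fixture(scope="session")
def default_bundle():
    """Default study-condition allotetraploid (10 outgroup chromosomes)."""
    return simulate_allotetraploid(SimConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def default_blocks(default_bundle):
    """Synteny blocks (focal-self and focal-outgroup) for the default bundle."""
    bundle = default_bundle
    ranks_f = synteny.build_gene_ranks(bundle.annotations["focal"])
    ranks_o = synteny.build_gene_ranks(bundle.annotations["outgroup"])
    params = synteny.SyntenyParams()
    self_hits = synteny.collapse_tandem_hits(
        synteny.filter_hits(hits_from_rows(bundle.hits["focal_self"])), ranks_f
    )
    blocks_self = synteny.chain_collinear_blocks(self_hits, ranks_f, None, params, within=True)
    blocks_og = synteny.chain_collinear_blocks(
        synteny.filter_hits(hits_from_rows(bundle.hits["focal_outgroup"])),
        ranks_f,
        ranks_o,
        params,
    )
    return {"self": blocks_self, "outgroup": blocks_og, "ranks_f": ranks_f, "ranks_o": ranks_o}


@pytest.fixture(scope="session")
def expression_bundle():
    """A wider fixture (≈2000 homoeolog pairs, short genes) for expression
    tallies that need tight fraction estimates."""
    cfg = SimConfig(seed=FIXTURE_SEED, genes_per_chrom=300, gene_length_codons=30)
    bundle = simulate_allotetraploid(cfg)
    matrix, sheet = simulate_expression(bundle.truth, cfg, sorted(bundle.sequences["focal"]))
    return bundle, matrix, sheet, cfg


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    """Full default `run-all` on the simulated fixture."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(outdir=str(outdir), seed=FIXTURE_SEED, simulate={})
    report = run_pipeline(cfg)
    return report, outdir
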