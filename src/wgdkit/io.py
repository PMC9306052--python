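"""File formats: FASTA, GFF3/BED6, tabular homology hits, expression TSVs.

FASTA goes through Biopython; GFF3 writing/reading here covers the flat
gene-feature files this pipeline produces and consumes. Coordinates are
1-based inclusive in GFF3 and converted to the internal 0-based half-open
convention on read; BED6 is read natively.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import CodonPairAlignment
from .synteny import GeneModel, HomologyHit

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

KAKS_COLUMNS = [
    "gene1",
    "gene2",
    "n_codons_used",
    "S",
    "N",
    "Sd",
    "Nd",
    "Ks",
    "Ka",
    "omega",
    "n_4d_sites",
    "raw_4dtv",
    "corrected_4dtv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description="") for gid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_pairwise_fasta(path: str | Path) -> CodonPairAlignment:
    """An aligned FASTA holding exactly two in-frame records."""
    seqs = read_fasta(path)
    if len(seqs) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, found {len(seqs)}")
    (id1, s1), (id2, s2) = seqs.items()
    return CodonPairAlignment(id1, id2, s1, s2)


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write(
                f"{g.chromosome}\twgdkit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3(path: str | Path, feature_types: tuple[str, ...] = ("gene", "mRNA")) -> list[GeneModel]:
    """Gene models from a GFF3 file (gene features with an ID attribute)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name")
            if gid is None:
                raise ValueError(f"{path}: feature without ID attribute: {line!r}")
            strand = parts[6] if parts[6] in "+-" else "+"
            genes.append(
                GeneModel(gid, parts[0], int(parts[3]) - 1, int(parts[4]), strand)
            )
    return genes


def read_bed6(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        GeneModel(r.name_, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.rename(columns={"name": "name_"}).itertuples()
    ]


def read_hits(path: str | Path) -> list[HomologyHit]:
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS, comment="#")
    return [
        HomologyHit(
            str(r.qseqid),
            str(r.sseqid),
            float(r.bitscore),
            float(r.evalue),
            float(r.pident),
        )
        for r in df.itertuples()
    ]


def write_hit_rows(rows: list[tuple], path: str | Path) -> None:
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def kaks_table(results: list[dict]) -> pd.DataFrame:
    """Long-format Ka/Ks + 4DTv table; undefined estimates become NA."""
    return pd.DataFrame(results, columns=KAKS_COLUMNS)


def write_kaks_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_kaks_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"timepoint": str})
    required = {"sample", "tissue", "timepoint", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df
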