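"""Readers and writers for the pipeline's on-disk formats.

GFF3 (genes and TEs), FASTA (CDS), and TSV tables (methylation sites, TFBS
hits, counts, sample metadata, pair tables, feature tables).  GFF3 and
methylation positions are 1-based inclusive on disk; TE/TFBS interval tables
are BED-style 0-based half-open, matching the internal convention.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .context import METHYL_COLUMNS, TE_COLUMNS
from .pairing import AllelePair, GeneModel

__all__ = [
    "read_gff3_genes",
    "write_gff3_genes",
    "read_fasta",
    "write_fasta",
    "read_methylation",
    "write_methylation",
    "read_te_gff3",
    "write_te_gff3",
    "read_tfbs",
    "write_tfbs",
    "read_counts",
    "write_counts",
    "read_samples",
    "read_pairs",
    "write_pairs",
    "write_dataset",
]


# -- GFF3 gene models --------------------------------------------------------

def write_gff3_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for j, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t.\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{j};Parent={mrna}\n"
                )
                fh.write(
                    f"{g.chrom}\t.\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{j};Parent={mrna}\n"
                )


def read_gff3_genes(path: str | Path, haplotype: str = "A") -> list[GeneModel]:
    """Parse gene models from GFF3; one representative mRNA per gene, chosen
    as the one with the longest summed CDS (ties: lexicographic id)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        best = None
        for mrna in db.children(gene, featuretype="mRNA"):
            cds_len = sum(c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS"))
            key = (-cds_len, mrna.id)
            if best is None or key < best[0]:
                best = (key, mrna)
        if best is None:
            exons = [(gene.start, gene.end)]
        else:
            exon_feats = list(db.children(best[1], featuretype="exon"))
            if not exon_feats:
                exon_feats = list(db.children(best[1], featuretype="CDS"))
            exons = sorted((f.start, f.end) for f in exon_feats)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                haplotype=haplotype,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                start=gene.start,
                end=gene.end,
                exons=tuple(exons),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


# -- FASTA -------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# -- TSV tables --------------------------------------------------------------

def read_methylation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METHYL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"methylation table missing columns: {missing}")
    return df


def write_methylation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_te_gff3(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in df.iterrows():
            attrs = (
                f"ID=TE{i:06d};Classification={row['te_class']}/"
                f"{row['superfamily']};Name={row['family']}"
            )
            fh.write(
                f"{row['chrom']}\t.\ttransposable_element\t{int(row['start']) + 1}\t"
                f"{int(row['end'])}\t.\t+\t.\t{attrs}\n"
            )


def read_te_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            cls, _, superfam = attrs.get("Classification", "./.").partition("/")
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "te_class": cls,
                    "superfamily": superfam or cls,
                    "family": attrs.get("Name", superfam or cls),
                }
            )
    return pd.DataFrame(rows, columns=TE_COLUMNS)


def read_tfbs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tfbs(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_pairs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pairs(pairs: Iterable[AllelePair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "gene_a": p.gene_a,
                "gene_g": p.gene_g,
                "score": p.homology_score,
                "chain_id": p.chain_id or "",
            }
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


# -- whole synthetic dataset -------------------------------------------------

def write_dataset(dataset, outdir: str | Path) -> dict[str, Path]:
    """Serialize a synthetic dataset to the standard formats the real
    pipeline reads.  Returns the mapping of artifact name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name, fn):
        paths[name] = out / name
        fn(paths[name])

    save("genes_a.gff3", lambda p: write_gff3_genes(dataset.genes_a, p))
    save("genes_g.gff3", lambda p: write_gff3_genes(dataset.genes_g, p))
    save("cds.fasta", lambda p: write_fasta(dataset.cds, p))
    save("te_a.gff3", lambda p: write_te_gff3(dataset.te_a, p))
    save("te_g.gff3", lambda p: write_te_gff3(dataset.te_g, p))
    save("tfbs_a.tsv", lambda p: write_tfbs(dataset.tfbs_a, p))
    save("tfbs_g.tsv", lambda p: write_tfbs(dataset.tfbs_g, p))
    save("counts.tsv", lambda p: write_counts(dataset.counts, p))
    save(
        "lengths.tsv",
        lambda p: dataset.lengths.rename_axis("gene_id").to_frame().to_csv(p, sep="\t"),
    )
    save("samples.tsv", lambda p: dataset.samples.to_csv(p, sep="\t", index=False))
    save("pairs_truth.tsv", lambda p: dataset.pairs_truth.to_csv(p, sep="\t", index=False))
    save("truth.tsv", lambda p: dataset.truth.to_csv(p, sep="\t", index=False))
    if dataset.methylation_a is not None:
        save("methylation_a.tsv", lambda p: write_methylation(dataset.methylation_a, p))
        save("methylation_g.tsv", lambda p: write_methylation(dataset.methylation_g, p))
    return paths
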