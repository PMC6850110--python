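"""Gene annotation container, GFF3 input/output and genomic categorization.

Coordinates are 1-based inclusive throughout (GFF3 convention).  The
container keeps flat tables of gene spans and sub-features, which is ample
for desk-scale panels and keeps overlap queries simple and vectorizable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

#: the five mutually exclusive SNP categories
SNP_CATEGORIES = ("five_prime_utr", "cds", "intron", "three_prime_utr", "intergenic")

#: eQTL-interval categories, in precedence order
EQTL_CATEGORIES = ("exon", "intron", "utr1kb", "intergenic")


@dataclass
class GeneAnnotation:
    """Gene models: spans, exons, CDS and UTR features, transcripts.

    ``genes`` has columns ``gene_id, chrom, start, end, strand, tss, tes``;
    the feature tables (``exons``, ``cds``, ``utr5``, ``utr3``) have
    ``gene_id, chrom, start, end``; ``transcripts`` has
    ``transcript_id, gene_id, length, utr5_len, utr3_len``.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    cds: pd.DataFrame
    utr5: pd.DataFrame
    utr3: pd.DataFrame
    transcripts: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        row = self.genes.loc[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        r = row.iloc[0]
        return str(r.chrom), int(r.start), int(r.end)

    def tss(self, gene_id: str) -> tuple[str, int, str]:
        row = self.genes.loc[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        r = row.iloc[0]
        return str(r.chrom), int(r.tss), str(r.strand)


def _hits(table: pd.DataFrame, chrom: str, pos: int) -> bool:
    t = table
    m = (t["chrom"].astype(str) == str(chrom)) & (t["start"] <= pos) & (pos <= t["end"])
    return bool(m.any())


def annotate_snp(chrom: str, pos: int, annotation: GeneAnnotation) -> str:
    """Assign one of the five genomic categories to a SNP position.

    Precedence when features overlap: CDS, then UTR, then intron; a
    position inside a gene span but no exon is intronic; outside any gene
    it is intergenic.  An unknown chromosome warns and returns intergenic.
    """
    chroms = set(annotation.genes["chrom"].astype(str))
    if str(chrom) not in chroms:
        warnings.warn(f"SNP chromosome {chrom!r} absent from annotation")
        return "intergenic"
    if _hits(annotation.cds, chrom, pos):
        return "cds"
    if _hits(annotation.utr5, chrom, pos):
        return "five_prime_utr"
    if _hits(annotation.utr3, chrom, pos):
        return "three_prime_utr"
    if _hits(annotation.genes.rename(columns={}), chrom, pos):
        return "intron"
    return "intergenic"


def _any_overlap(table: pd.DataFrame, chrom: str, start: int, end: int) -> bool:
    t = table
    m = (
        (t["chrom"].astype(str) == str(chrom))
        & (t["start"] <= end)
        & (start <= t["end"])
    )
    return bool(m.any())


def interval_category(
    chrom: str, start: int, end: int,
    annotation: GeneAnnotation, utr_flank: int = 1000,
) -> str:
    """Genomic category of an interval: exon > intron > utr1kb > intergenic.

    ``utr1kb`` means the interval overlaps a window of ``utr_flank`` bp
    around any transcription start or termination site without touching an
    exon or intron of a gene body.
    """
    if _any_overlap(annotation.exons, chrom, start, end):
        return "exon"
    if _any_overlap(annotation.genes, chrom, start, end):
        return "intron"
    g = annotation.genes
    for anchor in ("tss", "tes"):
        win = pd.DataFrame({
            "chrom": g["chrom"],
            "start": g[anchor] - utr_flank,
            "end": g[anchor] + utr_flank,
        })
        if _any_overlap(win, chrom, start, end):
            return "utr1kb"
    return "intergenic"


# ---------------------------------------------------------------------------
# GFF3 I/O

def write_gff3(annotation: GeneAnnotation, path: str | Path) -> None:
    """Serialize the gene models to GFF3 (1-based inclusive)."""
    rows = []
    for _, g in annotation.genes.iterrows():
        rows.append((g.chrom, "gene", g.start, g.end, g.strand,
                     f"ID={g.gene_id}"))
        tx = annotation.transcripts.loc[
            annotation.transcripts["gene_id"] == g.gene_id]
        for _, t in tx.iterrows():
            rows.append((g.chrom, "mRNA", g.start, g.end, g.strand,
                         f"ID={t.transcript_id};Parent={g.gene_id}"))
            for table, ftype in ((annotation.exons, "exon"),
                                 (annotation.cds, "CDS"),
                                 (annotation.utr5, "five_prime_UTR"),
                                 (annotation.utr3, "three_prime_UTR")):
                feats = table.loc[table["gene_id"] == g.gene_id]
                for _, f in feats.iterrows():
                    rows.append((g.chrom, ftype, f.start, f.end, g.strand,
                                 f"Parent={t.transcript_id}"))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, ftype, start, end, strand, attrs in rows:
            fh.write(f"{chrom}\tzeaqtl\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n")


def read_gff3(path: str | Path) -> GeneAnnotation:
    """Load gene models from GFF3 via an in-memory gffutils database."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes, exons, cds, utr5, utr3, txs = [], [], [], [], [], []
    for g in db.features_of_type("gene"):
        strand = g.strand if g.strand in "+-" else "+"
        tss = g.start if strand == "+" else g.end
        tes = g.end if strand == "+" else g.start
        genes.append((g.id, str(g.seqid), g.start, g.end, strand, tss, tes))
        for t in db.children(g, featuretype="mRNA"):
            fl = {ft: list(db.children(t, featuretype=ft))
                  for ft in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR")}
            for f in fl["exon"]:
                exons.append((g.id, str(f.seqid), f.start, f.end))
            for f in fl["CDS"]:
                cds.append((g.id, str(f.seqid), f.start, f.end))
            for f in fl["five_prime_UTR"]:
                utr5.append((g.id, str(f.seqid), f.start, f.end))
            for f in fl["three_prime_UTR"]:
                utr3.append((g.id, str(f.seqid), f.start, f.end))
            length = sum(f.end - f.start + 1 for f in fl["exon"])
            u5 = sum(f.end - f.start + 1 for f in fl["five_prime_UTR"])
            u3 = sum(f.end - f.start + 1 for f in fl["three_prime_UTR"])
            txs.append((t.id, g.id, length, u5, u3))

    def frame(rows, cols):
        return pd.DataFrame(rows, columns=cols)

    feat_cols = ["gene_id", "chrom", "start", "end"]
    return GeneAnnotation(
        genes=frame(genes, ["gene_id", "chrom", "start", "end", "strand",
                            "tss", "tes"]),
        exons=frame(exons, feat_cols),
        cds=frame(cds, feat_cols),
        utr5=frame(utr5, feat_cols),
        utr3=frame(utr3, feat_cols),
        transcripts=frame(txs, ["transcript_id", "gene_id", "length",
                                "utr5_len", "utr3_len"]),
    )
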