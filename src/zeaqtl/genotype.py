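"""Genotype container, SNP quality control and VCF input/output.

Lines are fully homozygous inbreds, so dosages take values 0 (homozygous
reference), 2 (homozygous alternate) or NaN (missing).  Heterozygous calls
(dosage 1) can appear in raw input; :func:`filter_genotypes` masks them to
missing before applying the rate filters, mirroring the variant-calling
conventions of RNA-seq-derived SNP panels in inbred association panels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


class GenotypeError(ValueError):
    """Raised on malformed or degenerate genotype input."""


def snp_name(chrom: str | int, pos: int) -> str:
    """Canonical SNP identifier ``S{chrom}_{pos}``."""
    return f"S{chrom}_{pos}"


@dataclass
class GenotypeMatrix:
    """Lines x SNPs allele-dosage table with SNP coordinates.

    Attributes
    ----------
    line_ids : list of str
        Ordered line identifiers (rows of ``dosages``).
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt``;
        positions are 1-based and strictly increasing within a chromosome.
    dosages : numpy.ndarray
        ``(n_lines, n_snps)`` float array over {0, 1, 2, NaN}.
    """

    line_ids: list
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        n_lines, n_snps = self.dosages.shape
        if n_lines != len(self.line_ids) or n_snps != len(self.snps):
            raise GenotypeError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.line_ids)} lines / {len(self.snps)} SNPs"
            )
        if self.snps["snp_id"].duplicated().any():
            raise GenotypeError("duplicate SNP ids")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector of one SNP across lines."""
        idx = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(snp_id)
        return self.dosages[:, idx[0]]

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.line_ids),
            self.snps.loc[np.asarray(mask)].reset_index(drop=True),
            self.dosages[:, np.asarray(mask)].copy(),
        )


# ---------------------------------------------------------------------------
# per-SNP statistics

def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one dosage column over non-missing lines.

    The alternate-allele frequency is ``mean(dosage) / 2`` over non-missing
    calls; the MAF is ``min(p, 1 - p)``.
    """
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    if not ok.any():
        raise GenotypeError("MAF undefined: all calls missing")
    p = d[ok].mean() / 2.0
    return float(min(p, 1.0 - p))


def _column_mafs(dosages: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_genotypes(
    G: GenotypeMatrix,
    het_max: float = 0.10,
    miss_max: float = 0.60,
    maf_min: float = 0.02,
) -> GenotypeMatrix:
    """Mask heterozygotes and drop SNPs failing het / missing / MAF rules.

    Heterozygous calls are set to missing first.  A SNP is removed when its
    heterozygote rate exceeds ``het_max``, its missing rate (after the het
    mask) exceeds ``miss_max``, or its MAF over non-missing calls falls
    below ``maf_min`` (strictly: ``MAF < maf_min`` is discarded, equality
    is retained).
    """
    if G.n_snps == 0 or G.n_lines == 0:
        raise GenotypeError("cannot filter an empty genotype matrix")
    D = G.dosages.copy()
    het_rate = np.mean(D == 1, axis=0)
    D[D == 1] = np.nan
    miss_rate = np.mean(np.isnan(D), axis=0)
    all_missing = miss_rate == 1.0
    maf = np.where(all_missing, 0.0, _column_mafs(D))
    keep = (het_rate <= het_max) & (miss_rate <= miss_max) & (maf >= maf_min)
    out = GenotypeMatrix(list(G.line_ids), G.snps.loc[keep], D[:, keep])
    log.info("filter_genotypes: kept %d / %d SNPs", out.n_snps, G.n_snps)
    return out


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing dosages with the per-SNP modal dosage.

    A deliberately simple, deterministic imputation: each missing call takes
    the most frequent observed dosage at that SNP; a frequency tie resolves
    to the major allele's homozygous dosage, and a tie in allele counts
    resolves to the reference (dosage 0).  Accuracy is well below that of a
    haplotype-based imputer; downstream analyses here only require complete,
    deterministic dosages.
    """
    D = G.dosages.copy()
    for j in range(D.shape[1]):
        col = D[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise GenotypeError(
                f"cannot impute SNP {G.snps['snp_id'].iloc[j]}: all calls missing"
            )
        values, counts = np.unique(obs, return_counts=True)
        best = counts == counts.max()
        if best.sum() == 1:
            fill = values[np.argmax(counts)]
        else:
            # modal tie: take the major allele's dosage; allele-count tie -> ref
            alt_freq = obs.mean() / 2.0
            fill = 2.0 if alt_freq > 0.5 else 0.0
        col[miss] = fill
    log.info("impute_missing: modal fill (not a haplotype-based imputer)")
    return GenotypeMatrix(list(G.line_ids), G.snps.copy(), D)


def mask_heterozygotes(G: GenotypeMatrix) -> GenotypeMatrix:
    """Set heterozygous calls (dosage 1) to missing."""
    D = G.dosages.copy()
    D[D == 1] = np.nan
    return GenotypeMatrix(list(G.line_ids), G.snps.copy(), D)


def concordance(G1: GenotypeMatrix, G2: GenotypeMatrix) -> float:
    """Fraction of shared (line, SNP) cells with equal non-missing dosage."""
    lines = [l for l in G1.line_ids if l in set(G2.line_ids)]
    snps = [s for s in G1.snps["snp_id"] if s in set(G2.snps["snp_id"])]
    if not lines or not snps:
        raise GenotypeError("no overlapping lines and SNPs to compare")
    i1 = [G1.line_ids.index(l) for l in lines]
    i2 = [G2.line_ids.index(l) for l in lines]
    pos1 = {s: j for j, s in enumerate(G1.snps["snp_id"])}
    pos2 = {s: j for j, s in enumerate(G2.snps["snp_id"])}
    j1 = [pos1[s] for s in snps]
    j2 = [pos2[s] for s in snps]
    A = G1.dosages[np.ix_(i1, j1)]
    B = G2.dosages[np.ix_(i2, j2)]
    ok = ~np.isnan(A) & ~np.isnan(B)
    if not ok.any():
        raise GenotypeError("no comparable non-missing cells")
    return float(np.mean(A[ok] == B[ok]))


def merge_snp_sets(G_primary: GenotypeMatrix,
                   G_secondary: GenotypeMatrix) -> GenotypeMatrix:
    """Union of two SNP panels; overlapping loci keep the primary genotypes.

    The line universe is the union of both panels; a line absent from the
    contributing panel is missing at that SNP.  Output SNPs are sorted by
    (chromosome, position).  Conflicting ref/alt alleles at a shared locus
    trigger a warning and keep the primary alleles.
    """
    lines = list(G_primary.line_ids)
    lines += [l for l in G_secondary.line_ids if l not in set(G_primary.line_ids)]
    p_ids = set(G_primary.snps["snp_id"])

    shared = set(G_secondary.snps["snp_id"]) & p_ids
    if shared:
        p = G_primary.snps.set_index("snp_id").loc[sorted(shared)]
        s = G_secondary.snps.set_index("snp_id").loc[sorted(shared)]
        bad = (p["ref"].values != s["ref"].values) | (p["alt"].values != s["alt"].values)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} shared loci disagree on ref/alt; "
                "keeping primary alleles"
            )

    frames, blocks = [], []
    for G, ids in ((G_primary, None), (G_secondary, p_ids)):
        mask = np.ones(G.n_snps, dtype=bool) if ids is None else \
            ~G.snps["snp_id"].isin(ids).values
        frames.append(G.snps.loc[mask])
        block = np.full((len(lines), int(mask.sum())), np.nan)
        rows = [lines.index(l) for l in G.line_ids]
        block[rows, :] = G.dosages[:, mask]
        blocks.append(block)

    snps = pd.concat(frames, ignore_index=True)
    D = np.hstack(blocks)
    order = np.lexsort((snps["pos"].values, snps["chrom"].astype(str).values))
    return GenotypeMatrix(lines, snps.iloc[order], D[:, order])


# ---------------------------------------------------------------------------
# VCF input / output

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Serialize to a plain-text VCF 4.2 with GT-only FORMAT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zeaqtl\n")
        for chrom in pd.unique(G.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.line_ids)) + "\n")
        for j, snp in G.snps.iterrows():
            gts = [
                "./." if np.isnan(d) else _GT_CODE[float(d)]
                for d in G.dosages[:, j]
            ]
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.ref}\t{snp.alt}"
                "\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Heterozygous genotypes load as dosage 1; unknown genotypes as NaN.
    """
    vcf = VCF(str(path))
    lines = list(vcf.samples)
    rows, cols = [], []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    code = np.array([0.0, 1.0, np.nan, 2.0])
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        sid = rec.ID if rec.ID else snp_name(rec.CHROM, rec.POS)
        rows.append((sid, str(rec.CHROM), int(rec.POS), rec.REF, alt))
        cols.append(code[rec.gt_types])
    vcf.close()
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    D = np.column_stack(cols) if cols else np.empty((len(lines), 0))
    return GenotypeMatrix(lines, snps, D)
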