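"""eQTL region calling from per-gene association summary statistics.

Significant SNPs for a gene are chained into clusters (consecutive gap
below 5 kb, at least three members), candidate clusters whose lead SNPs
are in linkage disequilibrium (r2 > 0.1) are pruned keeping the more
significant one (ties keep the larger joint effect), surviving regions are
classified as local or distant with a 20-kb cutoff, and assigned a genomic
category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zeaqtl.annotation import GeneAnnotation, interval_category


@dataclass
class EQTLRegion:
    """A called regulatory interval for one gene at one stage."""

    chrom: str
    start: int
    end: int
    member_snps: list
    lead_snp: str
    gene_id: str
    lead_p: float
    joint_effect: float = np.nan
    locality: str = ""
    category: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if self.lead_snp not in self.member_snps:
            raise ValueError("lead SNP not among member SNPs")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_snps(self) -> int:
        return len(self.member_snps)


def cluster_candidates(
    sig_snps: pd.DataFrame,
    gap_bp: int = 5000,
    min_snps: int = 3,
    gene_id: str = "",
    stage: str = "",
    diameter: bool = False,
) -> list[EQTLRegion]:
    """Chain significant SNPs into candidate eQTL regions.

    ``sig_snps`` needs columns ``snp_id, chrom, pos, p`` (all significant
    for one gene).  Within a chromosome, consecutive SNPs with a gap
    strictly below ``gap_bp`` join one cluster; clusters with at least
    ``min_snps`` members are emitted, spanning first to last member.  The
    lead SNP minimizes p (ties: leftmost).  With ``diameter=True`` the
    cluster additionally splits so no member pair is ``gap_bp`` or more
    apart (a stricter, diameter-bounded variant).
    """
    if len(sig_snps) == 0:
        return []
    df = sig_snps.sort_values(["chrom", "pos"], kind="stable")
    out: list[EQTLRegion] = []
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        breaks = np.nonzero(np.diff(pos) >= gap_bp)[0]
        pieces = np.split(np.arange(len(pos)), breaks + 1)
        if diameter:
            pieces = [p for piece in pieces for p in _split_diameter(pos, piece, gap_bp)]
        for piece in pieces:
            if len(piece) < min_snps:
                continue
            sub = grp.iloc[piece]
            lead = sub.loc[sub["p"] == sub["p"].min()].iloc[0]
            out.append(EQTLRegion(
                chrom=str(chrom),
                start=int(sub["pos"].min()),
                end=int(sub["pos"].max()),
                member_snps=list(sub["snp_id"]),
                lead_snp=str(lead["snp_id"]),
                gene_id=gene_id,
                lead_p=float(lead["p"]),
                stage=stage,
            ))
    return out


def _split_diameter(pos: np.ndarray, piece: np.ndarray, gap_bp: int):
    """Greedy left-to-right split so each part spans under ``gap_bp``."""
    parts, cur = [], [piece[0]]
    for i in piece[1:]:
        if pos[i] - pos[cur[0]] >= gap_bp:
            parts.append(np.array(cur))
            cur = [i]
        else:
            cur.append(i)
    parts.append(np.array(cur))
    return parts


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two complete dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance dosage vector; r2 defined as 0")
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def joint_effect_r2(expr_gene: np.ndarray, member_dosages: np.ndarray) -> float:
    """Variance of expression explained jointly by a candidate's SNPs.

    Multiple-regression R^2 of the gene's expression on the member dosage
    columns; rank deficiency is handled by the least-squares pseudo-inverse.
    """
    y = np.asarray(expr_gene, dtype=float)
    D = np.atleast_2d(np.asarray(member_dosages, dtype=float))
    if D.shape[0] != y.size:
        D = D.T
    X = np.column_stack([np.ones(y.size), D])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return 1.0 - float(np.sum(resid ** 2)) / tss


def prune_candidates(
    candidates: list[EQTLRegion],
    dosage_of,
    expr_gene: np.ndarray,
    r2_max: float = 0.1,
    lead_mode: str = "lead",
) -> list[EQTLRegion]:
    """Drop LD-redundant candidate eQTLs of one gene.

    ``dosage_of(snp_id)`` must return the complete dosage vector of a SNP.
    Candidates are ordered by lead p ascending, then joint effect (R^2 of
    expression on member dosages) descending, then leftmost; walking that
    order, a candidate whose lead SNP has ``r2 > r2_max`` with an already
    kept candidate's lead is removed.  With ``lead_mode='mean'`` the mean
    pairwise r2 over member SNPs is used instead of lead-lead r2.  The
    surviving set is mutually below the threshold and independent of the
    input order.
    """
    if not candidates:
        return []
    for c in candidates:
        c.joint_effect = joint_effect_r2(
            expr_gene, np.column_stack([dosage_of(s) for s in c.member_snps])
        )
    order = sorted(
        candidates,
        key=lambda c: (c.lead_p, -c.joint_effect, str(c.chrom), c.start),
    )
    kept: list[EQTLRegion] = []
    for cand in order:
        redundant = False
        for k in kept:
            if lead_mode == "mean":
                pairs = [
                    ld_r2(dosage_of(a), dosage_of(b))
                    for a in cand.member_snps for b in k.member_snps
                ]
                r2 = float(np.mean(pairs))
            else:
                r2 = ld_r2(dosage_of(cand.lead_snp), dosage_of(k.lead_snp))
            if r2 > r2_max:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    kept.sort(key=lambda c: (str(c.chrom), c.start))
    return kept


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Base pairs strictly between two 1-based inclusive intervals (0 if they touch/overlap)."""
    if a_start > b_end:
        return a_start - b_end - 1
    if b_start > a_end:
        return b_start - a_end - 1
    return 0


def classify_local_distant(
    eqtl: EQTLRegion,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    cutoff_bp: int = 20000,
) -> str:
    """Label an eQTL local (within ``cutoff_bp`` of the gene span) or distant."""
    if str(eqtl.chrom) != str(gene_chrom):
        return "distant"
    gap = interval_gap(eqtl.start, eqtl.end, gene_start, gene_end)
    return "local" if gap <= cutoff_bp else "distant"


def eqtl_genomic_category(
    eqtl: EQTLRegion, annotation: GeneAnnotation, utr_flank: int = 1000
) -> str:
    """Genomic category of the eQTL interval (exon > intron > utr1kb > intergenic)."""
    return interval_category(eqtl.chrom, eqtl.start, eqtl.end,
                             annotation, utr_flank=utr_flank)


def eqtls_to_frame(eqtls: list[EQTLRegion]) -> pd.DataFrame:
    """BED-like summary table of called eQTLs."""
    rows = [
        (e.chrom, e.start, e.end, e.gene_id, e.lead_snp, e.lead_p,
         e.n_snps, e.joint_effect, e.locality, e.category, e.stage)
        for e in eqtls
    ]
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "gene_id", "lead_snp", "lead_p",
        "n_snps", "joint_effect", "locality", "category", "stage",
    ])
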