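"""Quantitative trait transcripts and candidate-gene integration.

For each gene j the QTT model regresses its expression on the kernel
phenotype alongside population structure and hidden-factor covariates:

    E_ij = u_j + alpha_j KL_i + sum_k beta_jk PC_ik + sum_k gamma_jk HF_ik + d_ij

A gene is phenotype-related when alpha_j deviates significantly from
zero; its direction follows the sign of alpha_j.  Candidate genes for the
trait are the intersection of eQTL-bearing genes, significant QTTs and
GWAS-covered genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from zeaqtl.annotation import GeneAnnotation
from zeaqtl.association import P_FLOOR


class TraitError(ValueError):
    pass


@dataclass
class QTTResult:
    """Per-gene fit of the phenotype regression."""

    gene_id: str
    u: float                      # intercept
    alpha: float                  # phenotype coefficient
    beta: np.ndarray              # PC coefficients
    gamma: np.ndarray             # hidden-factor coefficients
    p_alpha: float
    rss: float
    pearson_r: float              # simple correlation of expression with KL

    @property
    def direction(self) -> str:
        return "up" if self.alpha > 0 else "down"


def qtt_fit(
    expr_gene: np.ndarray,
    KL: np.ndarray,
    PCs: np.ndarray | None,
    HFs: np.ndarray | None,
    n_hidden: int = 2,
    gene_id: str = "",
) -> QTTResult:
    """Least-squares fit of one gene's QTT regression.

    Uses the top ``n_hidden`` hidden-factor columns.  ``p_alpha`` is the
    two-sided t-test of ``alpha = 0``.  Hidden-factor columns that make
    the design collinear are dropped with a warning.
    """
    y = np.asarray(expr_gene, dtype=float)
    kl = np.asarray(KL, dtype=float)
    n = y.size
    P = np.atleast_2d(np.asarray(PCs, dtype=float)) if PCs is not None and np.size(PCs) \
        else np.empty((n, 0))
    if P.shape[0] != n:
        P = P.T
    H = np.atleast_2d(np.asarray(HFs, dtype=float)) if HFs is not None and np.size(HFs) \
        else np.empty((n, 0))
    if H.shape[0] != n:
        H = H.T
    H = H[:, :n_hidden]

    X = np.column_stack([np.ones(n), kl, P, H])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        keep = []
        base = np.column_stack([np.ones(n), kl, P])
        for j in range(H.shape[1]):
            trial = np.column_stack([base] + [H[:, i] for i in keep] + [H[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                keep.append(j)
        warnings.warn(
            f"dropped {H.shape[1] - len(keep)} collinear hidden-factor column(s)"
        )
        H = H[:, keep]
        X = np.column_stack([np.ones(n), kl, P, H])

    p = X.shape[1]
    if n < p + 1:
        raise TraitError(f"need at least {p + 1} complete cases, have {n}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se_alpha = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    if se_alpha == 0:
        p_alpha = P_FLOOR
    else:
        t = coef[1] / se_alpha
        p_alpha = max(float(2.0 * stats.t.sf(abs(t), dof)), P_FLOOR)
    n_pc = P.shape[1]
    r = float(np.corrcoef(y, kl)[0, 1]) if y.std() > 0 and kl.std() > 0 else 0.0
    return QTTResult(
        gene_id=gene_id,
        u=float(coef[0]),
        alpha=float(coef[1]),
        beta=coef[2:2 + n_pc].copy(),
        gamma=coef[2 + n_pc:].copy(),
        p_alpha=p_alpha,
        rss=rss,
        pearson_r=r,
    )


def qtt_select(
    results: list[QTTResult],
    median_expr: dict,
    p_max: float = 0.05,
    expr_median_min: float = 1.0,
) -> set:
    """Significant QTT genes: ``p_alpha < p_max`` and median expression above cutoff.

    ``median_expr`` maps gene id to its population median abundance (FPKM
    scale by default).
    """
    return {
        r.gene_id for r in results
        if r.p_alpha < p_max and median_expr.get(r.gene_id, 0.0) > expr_median_min
    }


def snps_to_genes(
    sig_snps: pd.DataFrame,
    annotation: GeneAnnotation,
    flank: int = 0,
) -> set:
    """Genes whose (optionally flanked) span contains a significant SNP.

    ``sig_snps`` needs columns ``chrom, pos``.
    """
    genes = annotation.genes
    out = set()
    if len(sig_snps) == 0:
        return out
    for chrom, grp in sig_snps.groupby(sig_snps["chrom"].astype(str)):
        pos = np.sort(grp["pos"].to_numpy())
        sub = genes.loc[genes["chrom"].astype(str) == str(chrom)]
        lo = np.searchsorted(pos, sub["start"].to_numpy() - flank, side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy() + flank, side="right")
        out |= set(sub.loc[(hi - lo) > 0, "gene_id"])
    return out


def integrate_candidates(
    eqtl_genes: set,
    qtt_genes: set,
    gwas_genes: set,
    known_intervals: pd.DataFrame | None = None,
    annotation: GeneAnnotation | None = None,
) -> pd.DataFrame:
    """Three-way intersection of evidence sets into a candidate table.

    Monotone in each input: enlarging any evidence set never removes a
    candidate.  If ``known_intervals`` (columns ``chrom, start, end``) and
    an annotation are supplied, candidates overlapping those intervals are
    flagged ``in_known_qtl``.
    """
    common = sorted(eqtl_genes & qtt_genes & gwas_genes)
    df = pd.DataFrame({"gene_id": common})
    if known_intervals is not None and annotation is not None and len(df):
        flags = []
        for g in common:
            chrom, start, end = annotation.gene_span(g)
            ki = known_intervals
            hit = (
                (ki["chrom"].astype(str) == chrom)
                & (ki["start"] <= end)
                & (start <= ki["end"])
            ).any()
            flags.append(bool(hit))
        df["in_known_qtl"] = flags
    return df


def haplotype_test(
    values: np.ndarray, dosage_at_lead: np.ndarray
) -> tuple[dict, float, float]:
    """Welch t-test of a phenotype/expression between lead-SNP haplotypes.

    The two homozygous dosage classes (0 vs 2) partition the lines; each
    group needs at least two members.  Returns (group means, t, p).
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(dosage_at_lead, dtype=float)
    ok = ~np.isnan(v) & ~np.isnan(d)
    v, d = v[ok], d[ok]
    g0, g2 = v[d == 0], v[d == 2]
    if len(g0) < 2 or len(g2) < 2:
        raise TraitError("each haplotype group needs >= 2 lines")
    t, p = stats.ttest_ind(g0, g2, equal_var=False)
    if np.isnan(p):          # identical constant groups -> no divergence
        t, p = 0.0, 1.0
    means = {"ref": float(g0.mean()), "alt": float(g2.mean())}
    return means, float(t), float(p)
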