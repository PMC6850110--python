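"""Expression container, normalization and the staging-consistency check.

Counts are normalized with the DESeq-style median-of-ratios estimator and
converted to FPKM; per-gene values are mapped to normal scores before
association scans to blunt outliers and non-normality (the R ``qqnorm``
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionError(ValueError):
    """Raised on degenerate expression input."""


@dataclass
class ExpressionMatrix:
    """Genes x lines abundance with both count and FPKM representations."""

    gene_ids: list
    line_ids: list
    counts: np.ndarray
    fpkm: np.ndarray
    gene_lengths: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.gene_ids), len(self.line_ids))
        for name in ("counts", "fpkm"):
            a = getattr(self, name)
            if a.shape != shape:
                raise ExpressionError(f"{name} shape {a.shape} != {shape}")
        if len(self.gene_lengths) != len(self.gene_ids):
            raise ExpressionError("gene_lengths inconsistent with gene_ids")
        if np.any(np.asarray(self.gene_lengths) <= 0):
            raise ExpressionError("gene lengths must be positive")
        if not np.all(np.isfinite(self.fpkm)):
            raise ExpressionError("FPKM must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def gene_row(self, gene_id: str, which: str = "fpkm") -> np.ndarray:
        i = self.gene_ids.index(gene_id)
        return getattr(self, which)[i]


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios per-line size factors.

    For each gene with all-positive counts the geometric mean across lines
    is the reference; a line's factor is the median over those genes of
    count / reference.
    """
    counts = np.asarray(counts, dtype=float)
    allpos = np.all(counts > 0, axis=1)
    if not allpos.any():
        raise ExpressionError("no gene with all-positive counts")
    ref = np.exp(np.mean(np.log(counts[allpos]), axis=1))
    return np.median(counts[allpos] / ref[:, None], axis=0)


def fpkm(counts: np.ndarray, gene_lengths: np.ndarray,
         factors: np.ndarray | None = None) -> np.ndarray:
    """Fragments per kilobase per million on normalized counts.

    ``FPKM_gj = norm_count_gj * 1e9 / (length_g * norm_library_size_j)``
    where normalized counts are ``counts / factors`` and the library size
    is the per-line sum of normalized counts.
    """
    counts = np.asarray(counts, dtype=float)
    if factors is None:
        factors = np.ones(counts.shape[1])
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ExpressionError("size factors must be positive")
    norm = counts / factors[None, :]
    lib = norm.sum(axis=0)
    if np.any(lib <= 0):
        raise ExpressionError("zero library size")
    lengths = np.asarray(gene_lengths, dtype=float)
    return norm * 1e9 / (lengths[:, None] * lib[None, :])


def filter_expressed(expr: np.ndarray, min_median: float = 0.0) -> np.ndarray:
    """Boolean mask of genes whose across-line median exceeds ``min_median``."""
    return np.median(np.asarray(expr, dtype=float), axis=1) > min_median


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """Normal-scores transform of one gene's values (R ``qqnorm`` convention).

    Averaged ranks map to ``(r - a) / (n + 1 - 2a)`` with the Blom offset
    ``a = 3/8`` for ``n <= 10`` and ``a = 1/2`` otherwise, then through the
    standard normal quantile function.  An all-equal input returns zeros.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ExpressionError("rank_normalize needs at least 2 values")
    if np.all(v == v[0]):
        return np.zeros(n)
    a = 3.0 / 8.0 if n <= 10 else 0.5
    r = stats.rankdata(v, method="average")
    return stats.norm.ppf((r - a) / (n + 1.0 - 2.0 * a))


def rank_normalize_matrix(expr: np.ndarray) -> np.ndarray:
    """Apply :func:`rank_normalize` to each gene (row)."""
    expr = np.asarray(expr, dtype=float)
    return np.vstack([rank_normalize(row) for row in expr])


def staging_consistency(expr: np.ndarray, line_ids: list,
                        top_n: int = 1000) -> pd.DataFrame:
    """Per-line correlation with the mean profile of the top-expressed genes.

    Genes are ranked by population mean; each line's expression of the top
    ``top_n`` genes is correlated (Pearson) with the mean profile.  Lines
    classify as ``very_strong`` (r >= 0.8), ``strong`` (0.6 <= r < 0.8) or
    ``other``; a line with a constant profile is flagged (r = NaN).
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape[0] < top_n:
        raise ExpressionError(
            f"need >= {top_n} genes for the consistency check, have {expr.shape[0]}"
        )
    top = np.argsort(-expr.mean(axis=1), kind="stable")[:top_n]
    sub = expr[top]
    profile = sub.mean(axis=1)
    pc = profile - profile.mean()
    denom_p = np.sqrt((pc ** 2).sum())
    out = []
    for j, line in enumerate(line_ids):
        x = sub[:, j]
        xc = x - x.mean()
        denom_x = np.sqrt((xc ** 2).sum())
        if denom_x == 0 or denom_p == 0:
            out.append((line, np.nan, "flagged"))
            continue
        r = float((xc @ pc) / (denom_x * denom_p))
        cls = "very_strong" if r >= 0.8 else "strong" if r >= 0.6 else "other"
        out.append((line, r, cls))
    return pd.DataFrame(out, columns=["line_id", "r", "consistency"])


# ---------------------------------------------------------------------------
# TSV I/O (genes x lines, header row = line ids, first column = gene id)

def write_matrix_tsv(matrix: np.ndarray, gene_ids: list, line_ids: list,
                     path) -> None:
    df = pd.DataFrame(matrix, index=pd.Index(gene_ids, name="gene_id"),
                      columns=line_ids)
    # 17 significant digits: exact binary64 round trip
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip")
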