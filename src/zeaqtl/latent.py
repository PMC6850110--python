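"""Population structure and hidden expression factors.

Genotype principal components capture population stratification, a
normalized identity-by-state matrix captures genome-wide relatedness, and
hidden expression factors (a residual-PCA factor model) capture broad
non-genetic expression variability, playing the role that Bayesian factor
models such as PEER play in large eQTL studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


class LatentError(ValueError):
    pass


@dataclass
class LatentFactors:
    """Covariate blocks for association and QTT models."""

    pcs: np.ndarray          # lines x n_pcs, scaled by singular values
    kinship: np.ndarray      # lines x lines, in [0, 1]
    hidden: np.ndarray       # lines x K, variance-ordered


def genotype_pcs(dosages: np.ndarray, k: int = 3) -> np.ndarray:
    """Top-k principal components of the centered dosage matrix.

    Expects a complete (imputed) matrix, conventionally pre-filtered to
    SNPs with no missing calls and MAF above 0.05.  Components are
    eigenvectors of the line-by-line covariance scaled by their singular
    values, so Euclidean distances reflect genetic variance.
    """
    D = np.asarray(dosages, dtype=float)
    if np.isnan(D).any():
        raise LatentError("genotype PCs require complete dosages")
    X = D - D.mean(axis=0, keepdims=True)
    if k == 0:
        return np.empty((D.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if k > np.sum(s > 1e-9 * s[0]):
        raise LatentError(f"k={k} exceeds the rank of the dosage matrix")
    # sign convention: largest-magnitude loading positive
    pcs = U[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def kinship_ibs(dosages: np.ndarray) -> np.ndarray:
    """Min-rescaled identity-by-state kinship for homozygous dosages.

    The raw IBS similarity is the mean shared-allele fraction
    ``S_ij = mean_m(1 - |d_im - d_jm| / 2)``; the matrix is then rescaled
    so its smallest entry maps to 0 and exact identity maps to 1:
    ``K = (S - min S) / (1 - min S)``.
    """
    D = np.asarray(dosages, dtype=float)
    if np.isnan(D).any():
        raise LatentError("kinship requires complete dosages")
    n, m = D.shape
    if n == 1:
        return np.ones((1, 1))
    A = D / 2.0
    if np.isin(A, (0.0, 1.0)).all():
        # homozygous panel: |a_i - a_j| = a_i + a_j - 2 a_i a_j elementwise
        r = A.mean(axis=1)
        S = 1.0 - (r[:, None] + r[None, :] - 2.0 * (A @ A.T) / m)
    else:
        S = np.empty((n, n))
        block = max(1, int(2e6 // max(m, 1)))
        for i0 in range(0, n, block):
            i1 = min(n, i0 + block)
            diff = np.abs(D[i0:i1, None, :] - D[None, :, :]) / 2.0
            S[i0:i1] = 1.0 - diff.mean(axis=2)
    smin = S.min()
    if smin >= 1.0:
        return np.ones((n, n))
    K = (S - smin) / (1.0 - smin)
    return K


def ensure_psd(K: np.ndarray, max_jitter: float = 1e-8) -> np.ndarray:
    """Add a logged diagonal jitter (at most ``max_jitter``) if needed."""
    w = np.linalg.eigvalsh(K)
    if w.min() >= 0:
        return K
    jitter = min(max_jitter, float(-w.min()) * 1.01 + 1e-12)
    log.info("kinship jitter %.3g added to restore PSD", jitter)
    return K + jitter * np.eye(K.shape[0])


def hidden_factors(expr_normalized: np.ndarray, covariates: np.ndarray,
                   k: int = 10) -> np.ndarray:
    """Residual-PCA hidden expression factors.

    Each gene (row of ``expr_normalized``) is regressed on the supplied
    covariates (typically the genotype PCs plus an intercept, added here);
    the top-``k`` left singular vectors of the residual lines x genes
    matrix are returned, variance-ordered and orthogonal to the
    covariates.  This is a deterministic substitute for Bayesian factor
    models of expression heterogeneity.
    """
    E = np.asarray(expr_normalized, dtype=float)
    n_lines = E.shape[1]
    if k >= n_lines:
        raise LatentError(f"k={k} must be below the number of lines {n_lines}")
    X = np.column_stack([np.ones(n_lines), np.asarray(covariates, dtype=float)]) \
        if covariates is not None and np.size(covariates) else \
        np.ones((n_lines, 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise LatentError("covariates are rank-deficient")
    Q, _ = np.linalg.qr(X)
    R = E.T - Q @ (Q.T @ E.T)          # lines x genes residuals
    if k == 0:
        return np.empty((n_lines, 0))
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    hf = U[:, :k] * s[:k]
    for j in range(hf.shape[1]):
        i = np.argmax(np.abs(hf[:, j]))
        if hf[i, j] < 0:
            hf[:, j] = -hf[:, j]
    return hf
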