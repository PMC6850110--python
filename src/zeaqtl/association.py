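"""Mixed-linear-model and general-linear-model association scans.

The mixed model is ``y = X b + g x + u + e`` with ``Var(u) = sigma2_g K``
and ``Var(e) = sigma2_e I``.  Variance components are estimated once per
response by REML under the null (no SNP) model and then held fixed for
every SNP test (the P3D / EMMAX approximation), which reduces each SNP
test to generalized least squares after whitening by the eigendecomposition
of the kinship matrix.  The GLM scan is the same machinery with an
identity covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

P_FLOOR = 1e-300
_LOG_DELTA_BOUNDS = (-6.0, 6.0)


class AssociationError(ValueError):
    pass


@dataclass
class VarianceComponents:
    """Genetic and residual variance of the null mixed model."""

    sigma2_g: float
    sigma2_e: float

    @property
    def heritability_ratio(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0

    @property
    def delta(self) -> float:
        """Residual-to-genetic variance ratio used for whitening."""
        if self.sigma2_g <= 0:
            return 10 ** _LOG_DELTA_BOUNDS[1]
        return self.sigma2_e / self.sigma2_g


def kinship_eigen(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the kinship matrix, clipped to PSD.

    Returns ``(eigenvalues, eigenvectors)``; eigenvalues below a small
    negative tolerance raise, tiny negatives clip to zero.
    """
    K = np.asarray(K, dtype=float)
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-6 * max(1.0, s.max()):
        raise AssociationError("kinship matrix is not PSD")
    return np.clip(s, 0.0, None), U


def _design(X: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if X is None or np.size(X) == 0:
        return ones
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    return np.hstack([ones, X])


def fit_null_mlm(
    y: np.ndarray,
    X: np.ndarray | None,
    K: np.ndarray,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """REML variance components of the null model via 1-D optimization.

    The profile REML criterion is minimized over ``log10 delta`` with
    ``delta = sigma2_e / sigma2_g``, using the spectral decomposition of
    ``K`` so each evaluation is O(n p^2).  Deterministic.  When ``K = I``
    only the total variance is identified; the reported components then
    share the sample residual variance at an arbitrary ratio.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Xf = _design(X, n)
    p = Xf.shape[1]
    if eig is None:
        eig = kinship_eigen(K)
    s, U = eig
    yr = U.T @ y
    Xr = U.T @ Xf

    def neg2_reml(log10_delta: float) -> float:
        w = s + 10.0 ** log10_delta
        Xw = Xr / np.sqrt(w)[:, None]
        yw = yr / np.sqrt(w)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        rss = float(np.sum((yw - Xw @ beta) ** 2))
        sign, logdet_xtx = np.linalg.slogdet(XtX)
        if sign <= 0 or rss <= 0:
            return np.inf
        return (n - p) * np.log(rss) + float(np.sum(np.log(w))) + logdet_xtx

    res = optimize.minimize_scalar(
        neg2_reml, bounds=_LOG_DELTA_BOUNDS, method="bounded",
        options={"xatol": 1e-6},
    )
    delta = 10.0 ** float(res.x)
    w = s + delta
    Xw = Xr / np.sqrt(w)[:, None]
    yw = yr / np.sqrt(w)
    beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    sigma2_g = rss / max(n - p, 1)
    return VarianceComponents(sigma2_g=sigma2_g, sigma2_e=delta * sigma2_g)


def _scan_core(
    yw: np.ndarray, Gw: np.ndarray, Xw: np.ndarray,
    const_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP slope t-tests after whitening.

    Returns (beta, se, p) arrays; SNPs in ``const_mask`` (or collinear
    with the covariates) report beta 0, se NaN, p 1.
    """
    n, p = Xw.shape
    Q, _ = np.linalg.qr(Xw)
    yres = yw - Q @ (Q.T @ yw)
    Gres = Gw - Q @ (Q.T @ Gw)
    gg = np.einsum("ij,ij->j", Gres, Gres)
    gy = yres @ Gres
    dof = n - p - 1
    if dof <= 0:
        raise AssociationError("not enough observations for the scan")
    scale = np.median(gg[gg > 0]) if np.any(gg > 0) else 1.0
    degenerate = const_mask | (gg <= 1e-10 * max(scale, 1e-30))
    gg_safe = np.where(degenerate, 1.0, gg)
    beta = np.where(degenerate, 0.0, gy / gg_safe)
    rss = np.maximum(yres @ yres - beta ** 2 * gg_safe, 0.0)
    sigma2 = rss / dof
    se = np.sqrt(np.where(degenerate, np.nan, sigma2 / gg_safe))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, beta / se)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals = np.where(degenerate, 1.0, np.maximum(pvals, P_FLOOR))
    return beta, se, pvals


def _result_frame(snp_ids, beta, se, pvals, n_used, response_id=None):
    df = pd.DataFrame({
        "snp_id": snp_ids if snp_ids is not None else np.arange(len(beta)),
        "beta": beta, "se": se, "p": pvals, "n_used": n_used,
    })
    if response_id is not None:
        df.insert(1, "response_id", response_id)
    return df


def mlm_scan(
    y: np.ndarray,
    G: np.ndarray,
    X: np.ndarray | None,
    K: np.ndarray,
    vc: VarianceComponents,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    snp_ids=None,
    response_id=None,
    UtG: np.ndarray | None = None,
) -> pd.DataFrame:
    """P3D mixed-model scan: GLS slope t-test of each SNP column of ``G``.

    ``vc`` must come from :func:`fit_null_mlm` on the same response and
    covariates; whitening uses ``(K + delta I)^{-1/2}`` in the rotated
    basis, so supplying a precomputed ``eig`` (and optionally
    ``UtG = U.T @ G``) avoids repeated decompositions when scanning many
    responses against one genotype matrix.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = y.size
    Xf = _design(X, n)
    if eig is None:
        eig = kinship_eigen(K)
    s, U = eig
    w = s + vc.delta
    isw = 1.0 / np.sqrt(w)
    yw = isw * (U.T @ y)
    Xw = isw[:, None] * (U.T @ Xf)
    if UtG is None:
        UtG = U.T @ G
    Gw = isw[:, None] * UtG
    const_mask = np.nanstd(G, axis=0) == 0
    beta, se, pvals = _scan_core(yw, Gw, Xw, const_mask)
    return _result_frame(snp_ids, beta, se, pvals, n, response_id)


def glm_scan(
    y: np.ndarray,
    G: np.ndarray,
    X: np.ndarray | None = None,
    snp_ids=None,
    response_id=None,
) -> pd.DataFrame:
    """Per-SNP ordinary least-squares slope t-test (optional covariates)."""
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    Xf = _design(X, y.size)
    const_mask = np.nanstd(G, axis=0) == 0
    beta, se, pvals = _scan_core(y, G, Xf, const_mask)
    return _result_frame(snp_ids, beta, se, pvals, y.size, response_id)


def bh_select(p_values: np.ndarray, fdr: float = 0.05
              ) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up selection.

    Returns the boolean mask of significant tests (in input order) and the
    realized p-value cutoff (0.0 when nothing passes).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise AssociationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = fdr * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= crit)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    cutoff = ranked[passing[-1]]
    return p <= cutoff, float(cutoff)
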