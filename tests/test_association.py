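"""Mixed-model machinery: REML null fit, P3D scan, GLM scan, BH selection."""

import numpy as np
import pytest
from scipy import stats

from zeaqtl.association import (AssociationError, VarianceComponents,
                                bh_select, fit_null_mlm, glm_scan,
                                kinship_eigen, mlm_scan)


def random_kinship(n, rng):
    D = 2.0 * (rng.random((n, 300)) < rng.uniform(0.1, 0.9, size=300))
    A = D / 2.0
    r = A.mean(axis=1)
    S = 1.0 - (r[:, None] + r[None, :] - 2.0 * (A @ A.T) / 300)
    K = (S - S.min()) / (1.0 - S.min())
    w = np.linalg.eigvalsh(K)
    if w.min() < 0:
        K -= w.min() * 1.01 * np.eye(n) * -1.0
    return K


def draw_mixed(y_beta, X, K, h2, rng, noise=1.0):
    n = K.shape[0]
    s, U = np.linalg.eigh(K)
    u = U @ (np.sqrt(np.clip(s, 0, None)) * rng.normal(size=n))
    u = u / u.std() * np.sqrt(h2)
    e = rng.normal(size=n) * np.sqrt(1 - h2)
    base = X @ y_beta if X is not None else 0.0
    return base + u + e


class TestNullFit:
    def test_exact_fit_zero_residual(self):
        rng = np.random.default_rng(0)
        n = 50
        X = rng.normal(size=(n, 2))
        y = X @ [1.0, -2.0] + 3.0
        K = random_kinship(n, rng)
        vc = fit_null_mlm(y, X, K)
        assert vc.sigma2_g + vc.sigma2_e < 1e-8

    def test_identity_kinship_total_variance(self):
        # with K = I only the total variance is identified; it must match
        # the OLS residual variance
        rng = np.random.default_rng(1)
        n = 80
        y = rng.normal(size=n)
        vc = fit_null_mlm(y, None, np.eye(n))
        resid_var = y.var(ddof=1)
        assert vc.sigma2_g + vc.sigma2_e == pytest.approx(resid_var, rel=1e-3)

    def test_heritability_recovery(self):
        # h2 = 0.5 recovered within +-0.15 on average over 50 replicates
        rng = np.random.default_rng(2)
        n = 300
        K = random_kinship(n, rng)
        ratios = []
        for _ in range(50):
            y = draw_mixed(None, None, K, h2=0.5, rng=rng)
            vc = fit_null_mlm(y, None, K)
            ratios.append(vc.heritability_ratio)
        assert abs(np.mean(ratios) - 0.5) < 0.15


class TestMlmScan:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(3)
        n, m = 60, 40
        G = 2.0 * (rng.random((n, m)) < 0.4)
        y = rng.normal(size=n)
        K = np.eye(n)
        vc = fit_null_mlm(y, None, K)
        p_mlm = mlm_scan(y, G, None, K, vc)["p"].to_numpy()
        p_glm = glm_scan(y, G)["p"].to_numpy()
        assert np.max(np.abs(np.log10(p_mlm) - np.log10(p_glm))) < 1e-6

    def test_planted_effect_power(self):
        # beta=1, MAF 0.3, h2=0.3, n=300: median -log10 p over 20 reps > 6
        rng = np.random.default_rng(4)
        n = 300
        K = random_kinship(n, rng)
        logs = []
        for _ in range(20):
            g = 2.0 * (rng.random(n) < 0.3)
            y = draw_mixed(None, None, K, h2=0.3, rng=rng) + 1.0 * g
            vc = fit_null_mlm(y, None, K)
            p = mlm_scan(y, g[:, None], None, K, vc)["p"].iloc[0]
            logs.append(-np.log10(p))
        assert np.median(logs) > 6

    def test_null_uniform_ks(self):
        # permuted response: p-values uniform at 5000 independent SNPs
        rng = np.random.default_rng(5)
        n, m = 200, 5000
        G = 2.0 * (rng.random((n, m)) < rng.uniform(0.1, 0.9, size=m))
        K = random_kinship(n, rng)
        y = draw_mixed(None, None, K, h2=0.4, rng=rng)
        y = y[rng.permutation(n)]
        vc = fit_null_mlm(y, None, K)
        p = mlm_scan(y, G, None, K, vc)["p"].to_numpy()
        assert stats.kstest(p, "uniform").statistic < 0.05

    def test_constant_snp_flagged(self):
        rng = np.random.default_rng(6)
        n = 40
        G = np.column_stack([np.full(n, 2.0),
                             2.0 * (rng.random(n) < 0.5)])
        y = rng.normal(size=n)
        K = np.eye(n)
        vc = fit_null_mlm(y, None, K)
        res = mlm_scan(y, G, None, K, vc)
        assert res["p"].iloc[0] == 1.0 and res["beta"].iloc[0] == 0.0

    def test_p3d_close_to_exact_gls(self):
        # refitting variance components per SNP moves log10 p by < 0.5
        rng = np.random.default_rng(7)
        n = 200
        K = random_kinship(n, rng)
        s, U = kinship_eigen(K)
        G = 2.0 * (rng.random((n, 10)) < 0.4)
        y = draw_mixed(None, None, K, h2=0.5, rng=rng) + 0.3 * G[:, 0]
        vc0 = fit_null_mlm(y, None, K)
        p3d = mlm_scan(y, G, None, K, vc0, eig=(s, U))["p"].to_numpy()
        for j in range(10):
            # exact: variance components refit with the SNP in the model
            vc_j = fit_null_mlm(y, G[:, [j]], K, eig=(s, U))
            p_exact = mlm_scan(y, G[:, [j]], None, K, vc_j,
                               eig=(s, U))["p"].iloc[0]
            assert abs(np.log10(p3d[j]) - np.log10(p_exact)) < 0.5


class TestGlmScan:
    def test_exact_relationship(self):
        g = np.array([0.0, 0, 2, 2, 0, 2, 0, 2])
        res = glm_scan(g.copy(), g[:, None])
        assert res["beta"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] <= 1e-30

    def test_orthogonal_response(self):
        g = np.array([0.0, 0, 2, 2])
        y = np.array([-1.0, 1.0, -1.0, 1.0])   # orthogonal to g and intercept
        res = glm_scan(y, g[:, None])
        assert res["beta"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_stratification_inflates_glm_not_mlm(self):
        # a structured phenotype with no SNP effects: the GLM piles up
        # small p-values, the mixed model controls them
        from zeaqtl.genotype import impute_missing
        from zeaqtl.latent import genotype_pcs, kinship_ibs, ensure_psd
        from zeaqtl.simulate import simulate_dataset
        from tests.conftest import small_config

        ds = simulate_dataset(small_config(
            n_lines=200, n_subpops=2, fst_divergence=0.3, seed=21,
            n_cis_eqtl=0, n_trans_eqtl=0, n_shared=0, n_stage1_only=0,
            n_stage2_only=0, n_inverse=0, n_qtt_genes=0))
        G = impute_missing(ds.genotypes)
        rng = np.random.default_rng(22)
        y = 1.5 * (ds.truth.subpop == 0) + 0.5 * rng.normal(size=G.n_lines)
        p_glm = glm_scan(y, G.dosages)["p"].to_numpy()
        pcs = genotype_pcs(G.dosages, k=3)
        K = ensure_psd(kinship_ibs(G.dosages))
        vc = fit_null_mlm(y, pcs, K)
        p_mlm = mlm_scan(y, G.dosages, pcs, K, vc)["p"].to_numpy()
        n_glm = (p_glm < 1e-5).sum()
        n_mlm = (p_mlm < 1e-5).sum()
        assert n_glm >= 2 * max(n_mlm, 1)


def brute_force_bh(p, fdr):
    """Evaluate every step-up threshold explicitly."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= fdr * k / m:
            best_k = k
    if best_k == 0:
        return np.zeros(m, dtype=bool), 0.0
    cutoff = p[order[best_k - 1]]
    return np.asarray(p) <= cutoff, cutoff


class TestBhSelect:
    def test_worked_example(self):
        sig, cutoff = bh_select(np.array([0.001, 0.02, 0.8]), fdr=0.05)
        assert sig.tolist() == [True, True, False]
        assert cutoff == 0.02

    def test_all_ones_none(self):
        sig, cutoff = bh_select(np.ones(10))
        assert not sig.any() and cutoff == 0.0

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        for _ in range(50):
            m = int(rng.integers(1, 200))
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3.0)
            sig, cutoff = bh_select(p, fdr=0.05)
            bf_sig, bf_cut = brute_force_bh(p, 0.05)
            np.testing.assert_array_equal(sig, bf_sig)
            assert cutoff == bf_cut
            sm_sig = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(sig, sm_sig)

    def test_invalid_p_rejected(self):
        with pytest.raises(AssociationError):
            bh_select(np.array([0.0, 0.5]))
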