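"""End-to-end analysis pipeline and planted-truth recovery metrics.

``run_pipeline`` chains the full analysis on one dataset: genotype QC and
modal imputation, expression filtering and normal-scores transform,
population structure (PCs, IBS kinship) and hidden factors, per-gene
mixed-model eQTL scans with genome-wide BH selection, eQTL region calling
and pruning, cross-stage merging and inverse-effect detection, QTT
regression, kernel-length GWAS, candidate integration and motif
enrichment.  ``evaluate_recovery`` scores a pipeline run against the
simulator's truth table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zeaqtl import association as assoc
from zeaqtl import eqtl as eq
from zeaqtl import expression as xp
from zeaqtl import genotype as gt
from zeaqtl import latent as lt
from zeaqtl import stages as st
from zeaqtl import trait as tr
from zeaqtl.config import PipelineConfig
from zeaqtl.motifs import MOTIFS, motif_enrichment_report
from zeaqtl.report import summarize_run
from zeaqtl.simulate import STAGES, SimulatedDataset

log = logging.getLogger(__name__)


@dataclass
class StageScan:
    """Per-stage scan products."""

    stage: str
    gene_ids: list                 # expressed genes, row order of matrices
    expr_norm: np.ndarray          # genes x lines normal scores
    hidden: np.ndarray             # lines x K hidden factors
    p_matrix: np.ndarray           # genes x SNPs
    beta_matrix: np.ndarray
    bh_cutoff: float
    eqtls: list                    # final EQTLRegion list


@dataclass
class PipelineResult:
    config: PipelineConfig
    n_snps_raw: int
    genotypes: gt.GenotypeMatrix   # filtered + imputed
    pcs: np.ndarray
    kinship: np.ndarray
    scans: dict                    # stage -> StageScan
    merged: list
    sharing_counts: pd.Series
    shared_pairs: list             # (AllelicEffect, AllelicEffect) per stage pair
    inverse: list
    inverse_local: int
    multi_target: set
    qtt_results: list
    qtt_genes: set
    gwas_glm: pd.DataFrame
    gwas_mlm_n_sig: int
    gwas_genes: set
    eqtl_genes: set
    candidates: pd.DataFrame
    motif_reports: list
    summary: dict


def _snp_pos(snp_id: str) -> int:
    return int(str(snp_id).rsplit("_", 1)[1])


def scan_stage(
    expr_norm: np.ndarray,
    G: gt.GenotypeMatrix,
    X: np.ndarray,
    K: np.ndarray,
    eig=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mixed-model scan of every expressed gene against every SNP.

    Variance components refit per gene (P3D per response); the kinship
    eigendecomposition and rotated genotypes are shared across genes.
    Returns (p_matrix, beta_matrix), genes x SNPs.
    """
    if eig is None:
        eig = assoc.kinship_eigen(K)
    s, U = eig
    UtG = U.T @ G.dosages
    n_genes = expr_norm.shape[0]
    P = np.empty((n_genes, G.n_snps))
    B = np.empty((n_genes, G.n_snps))
    for i in range(n_genes):
        y = expr_norm[i]
        vc = assoc.fit_null_mlm(y, X, K, eig=eig)
        res = assoc.mlm_scan(y, G.dosages, X, K, vc, eig=eig, UtG=UtG)
        P[i] = res["p"].to_numpy()
        B[i] = res["beta"].to_numpy()
    return P, B


def call_stage_eqtls(
    P: np.ndarray,
    B: np.ndarray,
    gene_ids: list,
    G: gt.GenotypeMatrix,
    expr_norm: np.ndarray,
    annotation,
    cfg: PipelineConfig,
    stage: str,
) -> tuple[list, float]:
    """Genome-wide BH selection followed by per-gene region calling."""
    sig_mask, cutoff = assoc.bh_select(P.ravel(), fdr=cfg.fdr)
    sig_mask = sig_mask.reshape(P.shape)
    snp_lookup = {s: j for j, s in enumerate(G.snps["snp_id"])}

    def dosage_of(snp_id):
        return G.dosages[:, snp_lookup[snp_id]]

    gene_spans = annotation.genes.set_index("gene_id")
    eqtls = []
    for i, gene_id in enumerate(gene_ids):
        js = np.nonzero(sig_mask[i])[0]
        if js.size == 0:
            continue
        sig = pd.DataFrame({
            "snp_id": G.snps["snp_id"].to_numpy()[js],
            "chrom": G.snps["chrom"].to_numpy()[js],
            "pos": G.snps["pos"].to_numpy()[js],
            "p": P[i, js],
        })
        cands = eq.cluster_candidates(sig, gap_bp=cfg.gap_bp,
                                      min_snps=cfg.min_snps,
                                      gene_id=gene_id, stage=stage)
        final = eq.prune_candidates(cands, dosage_of, expr_norm[i],
                                    r2_max=cfg.ld_r2_max)
        if gene_id in gene_spans.index:
            grow = gene_spans.loc[gene_id]
            for e in final:
                e.locality = eq.classify_local_distant(
                    e, str(grow["chrom"]), int(grow["start"]),
                    int(grow["end"]), cutoff_bp=cfg.local_cutoff)
        for e in final:
            e.category = eq.eqtl_genomic_category(e, annotation,
                                                  utr_flank=cfg.utr_flank)
        eqtls.extend(final)
    return eqtls, cutoff


def run_pipeline(
    ds: SimulatedDataset,
    cfg: PipelineConfig | None = None,
    motif_targets: set | None = None,
) -> PipelineResult:
    """Execute the full integrated analysis on one dataset."""
    cfg = cfg or PipelineConfig()
    log.info("pipeline thresholds: %s", cfg.to_dict())

    # --- genotype QC ---------------------------------------------------
    n_raw = ds.genotypes.n_snps
    Gf = gt.filter_genotypes(ds.genotypes, het_max=cfg.het_max,
                             miss_max=cfg.miss_max, maf_min=cfg.maf_min)
    no_missing = ~np.isnan(Gf.dosages).any(axis=0)
    Gi = gt.impute_missing(Gf)

    # --- population structure -----------------------------------------
    struct_mask = no_missing & (gt._column_mafs(Gi.dosages) > cfg.struct_maf_min)
    if struct_mask.sum() < 10:
        struct_mask = gt._column_mafs(Gi.dosages) > cfg.struct_maf_min
    D_struct = Gi.dosages[:, struct_mask]
    pcs = lt.genotype_pcs(D_struct, k=cfg.n_pcs)
    K = lt.ensure_psd(lt.kinship_ibs(D_struct))
    eig = assoc.kinship_eigen(K)

    # --- per-stage expression prep + eQTL scan -------------------------
    scans: dict = {}
    for stage in STAGES:
        E = ds.expression[stage]
        expressed = xp.filter_expressed(E.fpkm, min_median=0.0)
        gene_ids = [g for g, keep in zip(E.gene_ids, expressed) if keep]
        expr_norm = xp.rank_normalize_matrix(E.fpkm[expressed])
        hidden = lt.hidden_factors(expr_norm, pcs, k=cfg.n_hidden)
        X = np.hstack([pcs, hidden])
        P, B = scan_stage(expr_norm, Gi, X, K, eig=eig)
        eqtls, cutoff = call_stage_eqtls(P, B, gene_ids, Gi, expr_norm,
                                         ds.annotation, cfg, stage)
        scans[stage] = StageScan(stage=stage, gene_ids=gene_ids,
                                 expr_norm=expr_norm, hidden=hidden,
                                 p_matrix=P, beta_matrix=B,
                                 bh_cutoff=cutoff, eqtls=eqtls)
        log.info("%s: %d eQTLs (BH cutoff %.3g)", stage, len(eqtls), cutoff)

    s1, s2 = STAGES

    # --- cross-stage comparison ----------------------------------------
    merged = st.merge_regions(scans[s1].eqtls, scans[s2].eqtls)
    sharing_counts = st.classify_stage_sharing(merged)
    snp_lookup = {s: j for j, s in enumerate(Gi.snps["snp_id"])}
    shared_pairs, pair_local = [], []
    for m in merged:
        if m.sharing != "shared":
            continue
        region_id = f"{m.chrom}:{m.start}-{m.end}"
        genes_both = m.genes(s1) & m.genes(s2)
        for g in sorted(genes_both):
            effects = []
            for stage in (s1, s2):
                sources = [e for e in m.sources[stage] if e.gene_id == g]
                lead_e = min(sources, key=lambda e: e.lead_p)
                E = ds.expression[stage]
                try:
                    afc = st.allelic_fold_change(
                        E.gene_row(g, "fpkm"),
                        Gi.dosages[:, snp_lookup[lead_e.lead_snp]],
                        eqtl_id=region_id, gene_id=g, stage=stage)
                except ValueError:
                    effects = []
                    break
                effects.append((afc, lead_e))
            if effects:
                shared_pairs.append((effects[0][0], effects[1][0]))
                pair_local.append(effects[0][1].locality == "local")
    inverse = st.detect_inverse(shared_pairs)
    inv_ids = {(a.eqtl_id, a.gene_id) for a, _ in inverse}
    inverse_local = sum(
        loc for (a, _), loc in zip(shared_pairs, pair_local)
        if (a.eqtl_id, a.gene_id) in inv_ids
    )

    # --- multi-target eQTLs --------------------------------------------
    region_genes = {
        f"{m.chrom}:{m.start}-{m.end}": {stage: m.genes(stage)
                                         for stage in m.sources}
        for m in merged
    }
    multi_target = st.flag_multi_target(region_genes,
                                        threshold=cfg.multi_target_min)

    # --- QTT ------------------------------------------------------------
    kl = ds.phenotype.to_numpy(dtype=float)
    scan1 = scans[s1]
    eqtl_genes = {e.gene_id for e in scan1.eqtls}
    E1 = ds.expression[s1]
    gene_row = {g: i for i, g in enumerate(scan1.gene_ids)}
    qtt_results = [
        tr.qtt_fit(scan1.expr_norm[gene_row[g]], kl, pcs, scan1.hidden,
                   n_hidden=cfg.n_hidden_qtt, gene_id=g)
        for g in sorted(eqtl_genes) if g in gene_row
    ]
    medians = {g: float(np.median(E1.gene_row(g, "fpkm")))
               for g in eqtl_genes if g in gene_row}
    qtt_genes = tr.qtt_select(qtt_results, medians, p_max=cfg.qtt_p,
                              expr_median_min=cfg.qtt_median)

    # --- kernel-length GWAS ---------------------------------------------
    gwas_glm = assoc.glm_scan(kl, Gi.dosages, snp_ids=Gi.snps["snp_id"])
    vc_kl = assoc.fit_null_mlm(kl, pcs, K, eig=eig)
    gwas_mlm = assoc.mlm_scan(kl, Gi.dosages, pcs, K, vc_kl, eig=eig,
                              snp_ids=Gi.snps["snp_id"])
    glm_sig = gwas_glm.loc[gwas_glm["p"] < cfg.gwas_p].copy()
    glm_sig["chrom"] = Gi.snps["chrom"].to_numpy()[glm_sig.index]
    glm_sig["pos"] = Gi.snps["pos"].to_numpy()[glm_sig.index]
    gwas_genes = tr.snps_to_genes(glm_sig, ds.annotation, flank=cfg.gene_flank)
    candidates = tr.integrate_candidates(eqtl_genes, qtt_genes, gwas_genes)

    # --- motif enrichment ------------------------------------------------
    if motif_targets is None:
        motif_targets = set(candidates["gene_id"]) if len(candidates) else \
            {g for rid in multi_target
             for genes in region_genes[rid].values() for g in genes}
    utr3_lens = dict(zip(ds.annotation.transcripts["transcript_id"],
                         ds.annotation.transcripts["utr3_len"]))
    motif_reports = []
    if motif_targets:
        for motif in sorted(MOTIFS):
            for region in ("mrna", "3utr"):
                motif_reports.append(motif_enrichment_report(
                    ds.transcripts, motif_targets, motif, region=region,
                    utr3_lens=utr3_lens))

    summary = summarize_run({
        "n_snps_raw": n_raw,
        "n_snps_filtered": Gi.n_snps,
        "eqtls_stage1": scans[s1].eqtls,
        "eqtls_stage2": scans[s2].eqtls,
        "sharing_counts": sharing_counts,
        "n_inverse": len(inverse),
        "n_inverse_local": inverse_local,
        "multi_target": multi_target,
        "n_qtt_significant": len(qtt_genes),
        "n_gwas_genes": len(gwas_genes),
        "n_eqtl_genes": len(eqtl_genes),
        "candidates": candidates,
        "motif_reports": motif_reports,
    })

    return PipelineResult(
        config=cfg, n_snps_raw=n_raw, genotypes=Gi, pcs=pcs, kinship=K,
        scans=scans, merged=merged, sharing_counts=sharing_counts,
        shared_pairs=shared_pairs, inverse=inverse,
        inverse_local=inverse_local, multi_target=multi_target,
        qtt_results=qtt_results, qtt_genes=qtt_genes, gwas_glm=gwas_glm,
        gwas_mlm_n_sig=int((gwas_mlm["p"] < cfg.gwas_p).sum()),
        gwas_genes=gwas_genes, eqtl_genes=eqtl_genes, candidates=candidates,
        motif_reports=motif_reports, summary=summary,
    )


# ---------------------------------------------------------------------------
# recovery metrics against the simulator's truth

def evaluate_recovery(result: PipelineResult, ds: SimulatedDataset) -> dict:
    """Score the pipeline's calls against the planted truth.

    Returns gene-level eQTL recall, the false-eQTL gene rate, cis/trans vs
    local/distant concordance of recovered eQTLs, inverse-effect recall
    and false-inverse rate, and candidate-gene recovery.
    """
    truth = ds.truth
    planted = truth.planted_eqtls
    called = {stage: result.scans[stage].eqtls for stage in STAGES}

    recovered, locality_ok, locality_n = 0, 0, 0
    for e in planted:
        pos = _snp_pos(e.snp_id)
        chrom = str(e.snp_id)[1:].rsplit("_", 1)[0]
        hit = False
        for stage in e.stages:
            for c in called[stage]:
                if c.gene_id == e.gene_id and str(c.chrom) == chrom \
                        and c.start <= pos <= c.end:
                    hit = True
                    locality_n += 1
                    want = "local" if e.kind == "cis" else "distant"
                    locality_ok += int(c.locality == want)
        recovered += int(hit)
    planted_genes = {e.gene_id for e in planted}
    false_genes = {
        c.gene_id for stage in STAGES for c in called[stage]
        if c.gene_id not in planted_genes
    }
    n_other = len(truth.gene_ids) - len(planted_genes)

    # inverse effects
    inv_truth = truth.inverse_pairs
    region_of = {}
    for a, b in result.inverse:
        region_of.setdefault(a.gene_id, []).append(a.eqtl_id)
    inv_found = 0
    for e in inv_truth:
        pos = _snp_pos(e.snp_id)
        chrom = str(e.snp_id)[1:].rsplit("_", 1)[0]
        for rid in region_of.get(e.gene_id, []):
            rchrom, span = rid.split(":")
            lo, hi = map(int, span.split("-"))
            if rchrom == chrom and lo <= pos <= hi:
                inv_found += 1
                break
    inv_truth_keys = {e.gene_id for e in inv_truth}
    flagged = {(a.eqtl_id, a.gene_id) for a, _ in result.inverse}
    n_eval_noninv = sum(
        1 for a, _ in result.shared_pairs if a.gene_id not in inv_truth_keys
    )
    n_false_inv = sum(
        1 for key in flagged if key[1] not in inv_truth_keys
    )

    qtt_planted = {g for g, _ in truth.qtt_genes}
    cand = set(result.candidates["gene_id"]) if len(result.candidates) else set()

    return {
        "eqtl_gene_recall": recovered / len(planted) if planted else np.nan,
        "false_eqtl_gene_rate": len(false_genes) / n_other if n_other else 0.0,
        "locality_concordance": locality_ok / locality_n if locality_n else np.nan,
        "inverse_recall": inv_found / len(inv_truth) if inv_truth else np.nan,
        "false_inverse_rate": (n_false_inv / n_eval_noninv
                               if n_eval_noninv else 0.0),
        "candidate_recall": (len(cand & qtt_planted) / len(qtt_planted)
                             if qtt_planted else np.nan),
        "false_candidate_rate": (
            len(cand - qtt_planted)
            / max(len(truth.gene_ids) - len(qtt_planted), 1)
        ),
        "n_candidates": len(cand),
    }


def null_scan_ks(ds: SimulatedDataset, cfg: PipelineConfig | None = None,
                 seed: int = 0) -> float:
    """KS distance from uniformity of MLM p-values under a permuted response.

    Permuting one gene's expression across lines breaks any
    genotype-expression link while keeping the marginal distribution, so
    the scan's p-values should be uniform.
    """
    from scipy import stats as sps

    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    Gf = gt.filter_genotypes(ds.genotypes, cfg.het_max, cfg.miss_max,
                             cfg.maf_min)
    Gi = gt.impute_missing(Gf)
    mask = gt._column_mafs(Gi.dosages) > cfg.struct_maf_min
    pcs = lt.genotype_pcs(Gi.dosages[:, mask], k=cfg.n_pcs)
    K = lt.ensure_psd(lt.kinship_ibs(Gi.dosages[:, mask]))
    E = ds.expression[STAGES[0]]
    y = xp.rank_normalize(E.fpkm[0])
    y = y[rng.permutation(y.size)]
    vc = assoc.fit_null_mlm(y, pcs, K)
    res = assoc.mlm_scan(y, Gi.dosages, pcs, K, vc)
    return float(sps.kstest(res["p"].to_numpy(), "uniform").statistic)
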