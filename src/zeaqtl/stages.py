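"""Cross-stage eQTL comparison.

eQTL regions called independently at two developmental stages are merged
by transitive interval intersection (keeping the maximal genomic span),
classified as stage-shared or stage-specific, profiled by distance to the
associated gene's TSS, and examined for inverse allelic effects — the
same lead-SNP allele pushing a gene's expression in opposite directions at
the two stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from zeaqtl.annotation import GeneAnnotation
from zeaqtl.eqtl import EQTLRegion


@dataclass
class MergedRegion:
    """Maximal span of a connected component of intersecting stage eQTLs."""

    chrom: str
    start: int
    end: int
    sources: dict          # stage -> list[EQTLRegion]

    @property
    def sharing(self) -> str:
        stages = [s for s, lst in self.sources.items() if lst]
        if len(stages) > 1:
            return "shared"
        return f"{stages[0]}_only"

    def genes(self, stage: str | None = None) -> set:
        if stage is not None:
            return {e.gene_id for e in self.sources.get(stage, [])}
        return {e.gene_id for lst in self.sources.values() for e in lst}


@dataclass
class AllelicEffect:
    """Major/minor-allele expression contrast at an eQTL lead SNP."""

    eqtl_id: str
    gene_id: str
    stage: str
    major_mean: float
    minor_mean: float

    @property
    def fold_change(self) -> float:
        return self.major_mean / self.minor_mean

    @property
    def log2fc(self) -> float:
        return float(np.log2(self.fold_change))


def merge_regions(eqtls_s1: list[EQTLRegion],
                  eqtls_s2: list[EQTLRegion]) -> list[MergedRegion]:
    """Merge intersecting eQTL intervals of both stages per chromosome.

    The merge is the transitive closure of pairwise intersection: each
    connected component becomes one region spanning min start to max end.
    Idempotent and independent of input order.
    """
    tagged = [(e.stage or "stage1", e) for e in eqtls_s1] + \
             [(e.stage or "stage2", e) for e in eqtls_s2]
    by_chrom: dict[str, list] = {}
    for stage, e in tagged:
        by_chrom.setdefault(str(e.chrom), []).append((stage, e))
    merged: list[MergedRegion] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[1].start, t[1].end))
        cur: list = []
        cur_start = cur_end = None
        for stage, e in items:
            if cur and e.start <= cur_end:
                cur.append((stage, e))
                cur_end = max(cur_end, e.end)
            else:
                if cur:
                    merged.append(_make_region(chrom, cur_start, cur_end, cur))
                cur = [(stage, e)]
                cur_start, cur_end = e.start, e.end
        if cur:
            merged.append(_make_region(chrom, cur_start, cur_end, cur))
    return merged


def _make_region(chrom, start, end, items) -> MergedRegion:
    sources: dict = {}
    for stage, e in items:
        sources.setdefault(stage, []).append(e)
    return MergedRegion(chrom=chrom, start=int(start), end=int(end),
                        sources=sources)


def classify_stage_sharing(merged: list[MergedRegion]) -> pd.Series:
    """Counts of merged regions by sharing class (partition of the set)."""
    classes = pd.Series([m.sharing for m in merged], dtype="object")
    counts = classes.value_counts()
    counts["total"] = len(merged)
    return counts


def tss_distance_profile(
    eqtls: list[EQTLRegion],
    annotation: GeneAnnotation,
    bin_bp: int = 5000,
    anchor: str = "midpoint",
) -> pd.DataFrame:
    """Signed eQTL-to-TSS distances and their binned density.

    Distance is measured from the eQTL midpoint (or lead-SNP position with
    ``anchor='lead'``) to the associated gene's TSS, oriented by strand so
    positive values lie downstream.  Returns one row per usable eQTL with
    columns ``gene_id, distance, bin``; eQTLs whose gene lacks a TSS are
    excluded and counted in ``df.attrs['n_missing_tss']``.
    """
    rows, missing = [], 0
    for e in eqtls:
        try:
            chrom, tss, strand = annotation.tss(e.gene_id)
        except KeyError:
            missing += 1
            continue
        if anchor == "lead":
            point = _lead_pos(e)
        else:
            point = (e.start + e.end) // 2
        if str(e.chrom) != chrom:
            continue
        dist = point - tss
        if strand == "-":
            dist = -dist
        rows.append((e.gene_id, dist, int(np.floor(dist / bin_bp)) * bin_bp))
    df = pd.DataFrame(rows, columns=["gene_id", "distance", "bin"])
    df.attrs["n_missing_tss"] = missing
    return df


def _lead_pos(e: EQTLRegion) -> int:
    # SNP ids are "S{chrom}_{pos}"
    return int(str(e.lead_snp).rsplit("_", 1)[1])


def allelic_fold_change(
    expr_gene: np.ndarray,
    dosage_at_lead: np.ndarray,
    eqtl_id: str = "",
    gene_id: str = "",
    stage: str = "",
    pseudo: float = 0.01,
) -> AllelicEffect:
    """Major- over minor-allele mean expression at a lead SNP.

    The major allele is the more frequent homozygous dosage class.  Means
    use non-missing lines only; a pseudo-count is added to both means when
    either is non-positive so the fold change stays defined.
    """
    expr = np.asarray(expr_gene, dtype=float)
    dose = np.asarray(dosage_at_lead, dtype=float)
    ok = ~np.isnan(dose) & ~np.isnan(expr)
    expr, dose = expr[ok], dose[ok]
    n_ref = int(np.sum(dose == 0))
    n_alt = int(np.sum(dose == 2))
    if n_ref < 2 or n_alt < 2:
        raise ValueError("each homozygous allele class needs >= 2 lines")
    major_d = 0.0 if n_ref >= n_alt else 2.0
    major = float(expr[dose == major_d].mean())
    minor = float(expr[dose == (2.0 - major_d)].mean())
    if major <= 0 or minor <= 0:
        major += pseudo
        minor += pseudo
    return AllelicEffect(eqtl_id=eqtl_id, gene_id=gene_id, stage=stage,
                         major_mean=major, minor_mean=minor)


def detect_inverse(
    shared_pairs: list[tuple[AllelicEffect, AllelicEffect]],
    min_effect: float = 0.0,
) -> list[tuple[AllelicEffect, AllelicEffect]]:
    """Stage-shared eQTL-gene pairs whose allelic effect flips sign.

    A pair is inverse when the log2 fold changes at the two stages have
    strictly opposite signs and both magnitudes exceed ``min_effect``; a
    zero log2 fold change at either stage is never inverse.
    """
    out = []
    for a, b in shared_pairs:
        fa, fb = a.log2fc, b.log2fc
        if fa == 0.0 or fb == 0.0:
            continue
        if np.sign(fa) == -np.sign(fb) and abs(fa) > min_effect \
                and abs(fb) > min_effect:
            out.append((a, b))
    return out


def local_enrichment_chisq(
    subset_local_count: int,
    subset_total: int,
    background_local_frac: float,
) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of a local/distant split.

    Compares the observed local/distant counts in a subset against the
    expectation under the background local fraction.
    """
    if subset_total <= 0:
        raise ValueError("subset_total must be positive")
    if not 0.0 < background_local_frac < 1.0:
        raise ValueError("background fraction must lie in (0, 1)")
    exp_local = subset_total * background_local_frac
    exp_dist = subset_total - exp_local
    if min(exp_local, exp_dist) < 1:
        warnings.warn("expected cell below 1; chi-square approximation weak")
    obs_local = subset_local_count
    obs_dist = subset_total - subset_local_count
    chi2 = (obs_local - exp_local) ** 2 / exp_local \
        + (obs_dist - exp_dist) ** 2 / exp_dist
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def flag_multi_target(eqtl_to_genes: dict, threshold: int = 3) -> set:
    """eQTLs associated with strictly more than ``threshold`` genes.

    ``eqtl_to_genes`` maps an eQTL id to either a per-stage dict of gene
    sets or a flat gene collection; the flag trips if any stage's gene
    count (or the flat count) exceeds the threshold.
    """
    flagged = set()
    for eqtl_id, genes in eqtl_to_genes.items():
        if isinstance(genes, dict):
            counts = [len(v) for v in genes.values()]
        else:
            counts = [len(set(genes))]
        if any(c > threshold for c in counts):
            flagged.add(eqtl_id)
    return flagged
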