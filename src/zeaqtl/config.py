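"""Configuration objects for the simulator and the analysis pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic two-stage eQTL panel.

    Defaults describe a desk-scale panel in the spirit of a maize
    association population: several hundred homozygous inbred lines drawn
    from a few diverged subpopulations, LD-blocked SNPs, expression at two
    kernel stages (5 and 15 days after pollination) with planted cis/trans
    eQTLs, hidden expression factors, and a kernel-length phenotype driven
    by a subset of transcripts.
    """

    n_lines: int = 300
    n_subpops: int = 3
    fst_divergence: float = 0.15
    n_chroms: int = 5
    snps_per_chrom: int = 1000
    ld_block_span: int = 5000
    n_genes: int = 500
    n_cis_eqtl: int = 40
    n_trans_eqtl: int = 20
    n_shared: int = 40
    n_stage1_only: int = 10
    n_stage2_only: int = 10
    n_inverse: int = 8
    eqtl_effect_sd: float = 1.5
    n_hidden_factors: int = 2
    n_qtt_genes: int = 8
    phenotype_noise_sd: float = 1.0
    motif_frac_target: float = 0.9
    motif_frac_background: float = 0.5
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            "n_lines n_subpops n_chroms snps_per_chrom ld_block_span n_genes "
            "n_cis_eqtl n_trans_eqtl n_shared n_stage1_only n_stage2_only "
            "n_inverse n_hidden_factors n_qtt_genes"
        ).split()
        for name in counts:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("n_lines", "n_subpops", "n_chroms", "snps_per_chrom",
                     "n_genes", "ld_block_span"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("fst_divergence", "motif_frac_target",
                     "motif_frac_background", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_inverse > self.n_shared:
            raise ConfigError("n_inverse cannot exceed n_shared")
        n_eqtl = self.n_cis_eqtl + self.n_trans_eqtl
        n_staged = self.n_shared + self.n_stage1_only + self.n_stage2_only
        if n_eqtl != n_staged:
            raise ConfigError(
                f"stage assignment ({n_staged}) must cover exactly the planted "
                f"eQTLs ({n_eqtl})"
            )
        if self.eqtl_effect_sd < 0 or self.phenotype_noise_sd < 0:
            raise ConfigError("effect and noise scales must be >= 0")


@dataclass
class PipelineConfig:
    """Thresholds and covariate dimensions of the analysis pipeline.

    Defaults follow the published kernel study settings: 5-kb SNP
    clustering with at least three significant SNPs, r2 > 0.1 candidate
    pruning, 20-kb local/distant cutoff, BH FDR 0.05 for eQTL scans, a
    fixed genome-wide cutoff of 1.29e-6 for the kernel-length GWAS,
    QTT selection at P < 0.05 with median expression > 1, multi-target
    flagging above three genes, three genotype PCs, ten hidden factors for
    association and two for the QTT regression, and a 1-kb UTR flank.
    """

    het_max: float = 0.10
    miss_max: float = 0.60
    maf_min: float = 0.02
    struct_maf_min: float = 0.05
    gap_bp: int = 5000
    min_snps: int = 3
    ld_r2_max: float = 0.1
    local_cutoff: int = 20000
    fdr: float = 0.05
    gwas_p: float = 1.29e-6
    qtt_p: float = 0.05
    qtt_median: float = 1.0
    multi_target_min: int = 3
    n_pcs: int = 3
    n_hidden: int = 10
    n_hidden_qtt: int = 2
    utr_flank: int = 1000
    top_n_consistency: int = 1000
    gene_flank: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_max", "miss_max", "maf_min", "struct_maf_min",
                     "fdr", "qtt_p", "ld_r2_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("gap_bp", "min_snps", "local_cutoff", "n_pcs",
                     "n_hidden", "n_hidden_qtt", "utr_flank"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_section(cls, data: dict, path):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in {path}: {sorted(unknown)}")
    return cls(**data)


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a :class:`SimConfig` from a YAML file (flat mapping)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _load_section(SimConfig, data, path)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a YAML file (flat mapping)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _load_section(PipelineConfig, data, path)
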