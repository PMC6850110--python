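"""Shared fixtures: small and study-scale simulated datasets."""

import numpy as np
import pytest

from zeaqtl.config import PipelineConfig, SimConfig
from zeaqtl.pipeline import evaluate_recovery, run_pipeline
from zeaqtl.simulate import simulate_dataset


def small_config(**overrides) -> SimConfig:
    """A fast desk-toy configuration for unit tests."""
    base = dict(
        n_lines=120, n_chroms=3, snps_per_chrom=150, n_genes=60,
        n_cis_eqtl=10, n_trans_eqtl=5, n_shared=9, n_stage1_only=3,
        n_stage2_only=3, n_inverse=3, n_qtt_genes=3,
        eqtl_effect_sd=3.0, phenotype_noise_sd=0.5, seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def tiny_run(tiny_dataset):
    return run_pipeline(tiny_dataset)


@pytest.fixture(scope="session")
def study_dataset():
    """Study-scale panel under the generator's default conditions."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def study_run(study_dataset):
    return run_pipeline(study_dataset)


@pytest.fixture(scope="session")
def study_metrics(study_run, study_dataset):
    return evaluate_recovery(study_run, study_dataset)


@pytest.fixture(scope="session")
def strong_dataset():
    """Study-scale panel with strong effects so every evidence chain has power."""
    return simulate_dataset(SimConfig(
        n_qtt_genes=3, eqtl_effect_sd=3.0, phenotype_noise_sd=0.5, seed=13,
    ))


@pytest.fixture(scope="session")
def strong_run(strong_dataset):
    return run_pipeline(strong_dataset)
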