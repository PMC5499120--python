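from dataclasses import replace

import pytest

from polyasym import AnalysisConfig, SyntheticConfig, generate_genome
from polyasym.analysis_pipeline import bundle_from_synthetic


def small_analysis_config(**kw):
    kw.setdefault("min_sample_n", 20)
    kw.setdefault("n_boot", 100)
    kw.setdefault("maxent_order", 1)
    return AnalysisConfig(**kw)


@pytest.fixture(scope="session")
def small_cfg():
    return small_analysis_config()


@pytest.fixture(scope="session")
def null_genome():
    """Small symmetric-composition genome with no planted depletion."""
    return generate_genome(SyntheticConfig(
        n_genes=120, exons_per_gene_law=("constant", 4), seed=101))


@pytest.fixture(scope="session")
def null_bundle(null_genome, small_cfg):
    return bundle_from_synthetic(null_genome, small_cfg)


@pytest.fixture(scope="session")
def depleted_genome():
    """500-gene genome with q = 0.5 distance-independent AATAAA depletion."""
    return generate_genome(SyntheticConfig(
        n_genes=500, exons_per_gene_law=("constant", 5),
        depletion_base_q=0.5, seed=202))


@pytest.fixture(scope="session")
def depleted_bundle(depleted_genome, small_cfg):
    return bundle_from_synthetic(depleted_genome, small_cfg)
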