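import dataclasses

import pytest

from grscad.grs import compute_weighted_grs
from grscad.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def study_config() -> SimConfig:
    """Default study-scale configuration (n=1414, 42 SNPs, one HWE violation)."""
    return SimConfig(n_subjects=1414, hwe_violation_snps=(7,), seed=11)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    return generate_cohort(study_config)


@pytest.fixture(scope="session")
def clean_cohort():
    """Mid-sized cohort with no injected QC problems."""
    return generate_cohort(SimConfig(n_subjects=2000, seed=4))


@pytest.fixture(scope="session")
def clean_grs(clean_cohort):
    return compute_weighted_grs(clean_cohort.genotypes, clean_cohort.panel)


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort at default (study) effect sizes, for recovery checks."""
    return generate_cohort(SimConfig(n_subjects=100_000, seed=3))


@pytest.fixture(scope="session")
def big_grs(big_cohort):
    return compute_weighted_grs(big_cohort.genotypes, big_cohort.panel)


@pytest.fixture(scope="session")
def pure_mediation_cohort():
    """Large cohort where the score acts on severity only through T2D."""
    cfg = dataclasses.replace(SimConfig(n_subjects=100_000, seed=13),
                              beta_direct=0.0)
    return generate_cohort(cfg)
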