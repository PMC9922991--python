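import numpy as np
import pandas as pd
import pytest

from twasmr import SimulationConfig, simulate_cohort, simulate_genotypes


@pytest.fixture(scope="session")
def small_cohort():
    """A modest family cohort with 5 forward-causal genes out of 40."""
    cfg = SimulationConfig(
        n_subjects=400, n_families=100, sibs_per_family=2, n_snps=50,
        n_genes=40, n_causal=5, scenario="forward", theta=0.5, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    cfg = SimulationConfig(
        n_subjects=500, n_families=0, sibs_per_family=1, n_snps=30,
        n_genes=60, scenario="null", seed=23,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def genotypes_only():
    cfg = SimulationConfig(n_subjects=300, n_families=60, sibs_per_family=3,
                           n_snps=25, n_genes=10, seed=5)
    return simulate_genotypes(cfg), cfg
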