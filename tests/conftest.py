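"""Shared fixtures: small, fast simulated datasets for unit tests.

Expensive full-scale runs live in test_acceptance.py; everything here uses a
short history on a short chromosome so each fixture builds in well under a
second.
"""

import numpy as np
import pytest

from mixp.popsim import PedigreeSpec, SimConfig, simulate_dataset


def tiny_sim_config(**overrides) -> SimConfig:
    """Short history / short chromosome, equilibrium theta around 100."""
    base = dict(
        effective_size=100,
        n_generations_history=300,
        genome_length_bp=1_000_000,
        mutation_rate=2.5e-7,
        genome_length_morgan=1.0,
        n_qtl=10,
        n_markers=100,
        h2_chr=0.3,
    )
    base.update(overrides)
    return SimConfig(**base)


TINY_PEDIGREE = PedigreeSpec(
    n_total=300, n_generations=4, n_genotyped=160,
    n_training=120, n_evaluation=40,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """One small end-to-end simulated dataset shared across tests."""
    return simulate_dataset(tiny_sim_config(), TINY_PEDIGREE, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
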