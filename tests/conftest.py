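import numpy as np
import pytest

from osn_identity.simulate import (
    ORFamilySpec,
    OSNSimSpec,
    simulate_or_family,
    simulate_osn_counts,
)


@pytest.fixture(scope="session")
def small_family():
    """A 40-receptor family with mostly-cis duplication."""
    return simulate_or_family(
        ORFamilySpec(n_receptors=40, alignment_length=150, cis_duplication_prob=0.8, seed=11)
    )


@pytest.fixture(scope="session")
def small_sc(small_family):
    """A small single-cell dataset with strong population structure."""
    return simulate_osn_counts(
        small_family,
        OSNSimSpec(
            n_genes=200,
            cells_per_population_mean=8,
            cells_per_population_dispersion=0.3,
            program_scale=1.0,
            sequence_coupling=0.5,
            seed=12,
        ),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
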