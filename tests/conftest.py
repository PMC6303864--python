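import numpy as np
import pytest

from gwpnet import GenotypeMatrix, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_genotypes():
    """4 samples x 3 markers covering every dosage class."""
    return GenotypeMatrix(
        dosages=np.array([[0, 1, 2], [1, 2, 0], [2, 0, 1], [0, 0, 2]]),
        sample_ids=np.array(["s1", "s2", "s3", "s4"], dtype=object),
        marker_ids=np.array(["m1", "m2", "m3"], dtype=object),
    )


def small_sim_config(**overrides):
    """A fast simulator configuration for pipeline-level tests."""
    base = dict(
        n=300,
        p=40,
        n_chromosomes=2,
        n_controlled=2,
        n_random=3,
        n_epistatic_pairs=1,
        n_dominance=1,
        n_overdominance=1,
        n_underdominance=1,
        h2=0.5,
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def small_sim():
    return simulate_dataset(small_sim_config())
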