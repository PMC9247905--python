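import numpy as np
import pytest

from foldswitch.fixtures import (SimulationConfig, simulate_genome,
                                 simulate_structures, simulate_superfamily)


@pytest.fixture(scope="session")
def superfamily():
    """The reference synthetic cohort: 100 sequences, half planted switchers."""
    return simulate_superfamily(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def null_superfamily():
    """Same conditions with no planted fold switchers."""
    return simulate_superfamily(SimulationConfig(seed=7, fold_switch_fraction=0.0))


@pytest.fixture(scope="session")
def structure_fixtures():
    return simulate_structures()


@pytest.fixture(scope="session")
def genome_fixture():
    return simulate_genome()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
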