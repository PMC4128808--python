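import numpy as np
import pytest

from fitland.contacts import build_contact_map, contact_vector
from fitland.synth import SynthConfig, make_toy_chain, make_vector_cohort


@pytest.fixture(scope="session")
def toy_chain():
    """30-residue compact synthetic chain."""
    return make_toy_chain(30, seed=42)


@pytest.fixture(scope="session")
def toy_map(toy_chain):
    return build_contact_map(toy_chain, cutoff=4.5, min_separation=2)


@pytest.fixture(scope="session")
def toy_vector(toy_chain, toy_map):
    return contact_vector(toy_chain.sequence, toy_map)


@pytest.fixture(scope="session")
def small_cohort():
    """Separable synthetic cohort shared across training tests."""
    return make_vector_cohort(
        SynthConfig(n_natives=24, decoys_per_native=12, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
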