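import numpy as np
import pytest
from hypothesis import settings

from riboforma import (
    ProteinSequence,
    Proteoform,
    SimulationConfig,
    load_modification_registry,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return load_modification_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(2018)


def random_protein(rng, length, identifier="P1"):
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    return ProteinSequence(identifier, "".join(rng.choice(aa, size=length)))


@pytest.fixture()
def ga_proteoform():
    return Proteoform(base=ProteinSequence("GA", "GA"))
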