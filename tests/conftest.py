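import numpy as np
import pytest

from cordaflux.dependency import CordaParams
from cordaflux.fixtures import (
    make_detox_motif,
    make_flexible_core_fixture,
    make_linear_chain,
)
from cordaflux.model import MetabolicModel, Metabolite, Reaction


@pytest.fixture
def params():
    return CordaParams(seed=7)


@pytest.fixture
def chain3():
    return make_linear_chain(3)


@pytest.fixture
def detox():
    return make_detox_motif()


@pytest.fixture
def flexcore():
    return make_flexible_core_fixture(2)


@pytest.fixture
def reversible_model():
    """A <=> B chain with open exchanges, one reversible internal step."""
    mets = [Metabolite("A[c]"), Metabolite("B[c]")]
    rxns = [
        Reaction("E_A", {"A[c]": 1.0}, -10.0, 10.0),
        Reaction("R_AB", {"A[c]": -1.0, "B[c]": 1.0}, -10.0, 10.0),
        Reaction("E_B", {"B[c]": -1.0}, -10.0, 10.0),
    ]
    return MetabolicModel(mets, rxns, id="rev")


@pytest.fixture
def rng():
    return np.random.default_rng(11)
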