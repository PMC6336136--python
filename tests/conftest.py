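import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from vtacircuit import (
    CircuitParams,
    LearnableWeights,
    ReceptorParams,
    TrialProtocol,
)
from vtacircuit.plasticity import LearningRates


@pytest.fixture(scope="session")
def params() -> CircuitParams:
    return CircuitParams()


@pytest.fixture(scope="session")
def receptor_params() -> ReceptorParams:
    return ReceptorParams()


@pytest.fixture(scope="session")
def protocol() -> TrialProtocol:
    return TrialProtocol()


@pytest.fixture(scope="session")
def rates() -> LearningRates:
    return LearningRates()


@pytest.fixture
def naive_weights() -> LearnableWeights:
    return LearnableWeights()
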