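import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radrepair import CellPhenotype, ModelParameters

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def human() -> CellPhenotype:
    return CellPhenotype()


@pytest.fixture(scope="session")
def human_nhej_defective() -> CellPhenotype:
    return CellPhenotype(nhej_competent=False, name="nhej_def")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20160914)
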