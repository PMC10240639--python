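import numpy as np
import pytest

from pfjforce.model import PlanarModel
from pfjforce.pfj_model import PatellarMechanism
from pfjforce.synthetic_cohort import CohortDesign


@pytest.fixture(scope="session")
def model() -> PlanarModel:
    return PlanarModel.from_yaml()


@pytest.fixture(scope="session")
def mechanism() -> PatellarMechanism:
    return PatellarMechanism.from_yaml()


@pytest.fixture(scope="session")
def design() -> CohortDesign:
    return CohortDesign.from_yaml()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_trial(design, model):
    """One noiseless ACLR signal-level trial shared across tests."""
    from pfjforce.synthetic_cohort import NoiseSpec, generate_signal_trial

    return generate_signal_trial(design, "ACLR", NoiseSpec(), seed=11, model=model,
                                 velocity=3.7)
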