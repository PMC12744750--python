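import numpy as np
import pytest

from cuprobe import BindingModel, OpticalModel, constants


@pytest.fixture(scope="session")
def bca_model() -> BindingModel:
    return BindingModel("BCA", 2, constants.BCA_BETA2)


@pytest.fixture(scope="session")
def pls_model() -> BindingModel:
    return BindingModel("PLS", 2, constants.PLS_BETA2)


@pytest.fixture(scope="session")
def atx1_model() -> BindingModel:
    return BindingModel.one_to_one_from_kd("ATX1", constants.ATX1_KD)


@pytest.fixture(scope="session")
def optics() -> OpticalModel:
    return OpticalModel(epsilon_probe_complex=constants.BCA_EPSILON_358)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
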