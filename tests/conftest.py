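import numpy as np
import pytest
from hypothesis import settings

from ganglion import ml_preset, rgc_preset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def repetitive():
    return rgc_preset("repetitive")


@pytest.fixture(scope="session")
def tonic():
    return rgc_preset("tonic")


@pytest.fixture(scope="session")
def phasic():
    return rgc_preset("phasic")


@pytest.fixture(scope="session")
def ml1():
    return ml_preset("I")


@pytest.fixture(scope="session")
def ml2():
    return ml_preset("II")


@pytest.fixture(scope="session")
def ml3():
    return ml_preset("III")


@pytest.fixture(scope="session")
def all_presets(repetitive, tonic, phasic, ml1, ml2, ml3):
    return {
        "repetitive": repetitive,
        "tonic": tonic,
        "phasic": phasic,
        "ml_class1": ml1,
        "ml_class2": ml2,
        "ml_class3": ml3,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160923)
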