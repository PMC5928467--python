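import numpy as np
import pytest

from leafgasket import GASKET_PRESETS, GasketSpec


@pytest.fixture(scope="session")
def gasket() -> GasketSpec:
    """The built-in circular 2 cm^2 fluorometer-head gasket."""
    return GASKET_PRESETS["6400-40"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20180424)
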