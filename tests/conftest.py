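import numpy as np
import pytest

from idpdesign import default_scaler, load_parameter_table


@pytest.fixture(scope="session")
def params():
    return load_parameter_table()


@pytest.fixture(scope="session")
def scaler(params):
    return default_scaler(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
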