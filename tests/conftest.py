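import numpy as np
import pytest

from aslquant.models import PASLKineticParams, PCASLParams
from aslquant.synthetic import CompartmentValues, make_phantom, make_ti_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def tis():
    return make_ti_grid()


@pytest.fixture
def pasl_params():
    return PASLKineticParams(t1_blood=1.9)


@pytest.fixture
def pcasl_params():
    return PCASLParams(t1_blood=1.8)


@pytest.fixture
def phantom():
    return make_phantom(matrix=(32, 32, 6), seed=0, values=CompartmentValues())
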