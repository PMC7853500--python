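import numpy as np
import pytest

from thalcort.model import build_default_model, find_steady_state
from thalcort.observation import ObservationParams


@pytest.fixture(scope="session")
def default_spec():
    return build_default_model()


@pytest.fixture(scope="session")
def default_rest(default_spec):
    return find_steady_state(default_spec, default_spec.u_baseline)


@pytest.fixture(scope="session")
def default_obs():
    return ObservationParams(gain=20.0)


@pytest.fixture(scope="session")
def t_grid():
    return np.arange(0.0, 301.0)
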