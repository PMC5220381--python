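import numpy as np
import pytest

import thalatrack.model as tc
from thalatrack.experiments import filter_parameters
from thalatrack.linearize import build_cetc


@pytest.fixture(scope="session")
def params():
    return tc.default_parameters()


@pytest.fixture(scope="session")
def rest(params):
    return tc.rest_state(params)


@pytest.fixture(scope="session")
def cetc_build(params):
    """CETC gating set and its approximation report at the default 16 segments."""
    return build_cetc(params.gating, n_segments=16)


@pytest.fixture(scope="session")
def cetc_params(cetc_build, params):
    return params.with_gating(cetc_build[0])


@pytest.fixture(scope="session")
def normal_trajectory(params):
    """1 s of square-wave-driven relay activity in the normal state."""
    return tc.simulate(params, tc.GpiInputSpec(mode="normal"),
                       tc.StimulusSpec(kind="square_wave"), 1000.0)
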