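import numpy as np
import pytest

from thymosim import (CALIBRATION_INFANT_CAPACITIES, HomeostasisParams,
                      InvolutionParams, SimulationSettings)


@pytest.fixture(scope="session")
def inv_params():
    return InvolutionParams()


@pytest.fixture(scope="session")
def base_params():
    return HomeostasisParams()


@pytest.fixture(scope="session")
def infant_caps():
    """Fixed infant calibration capacities (cortex, medulla)."""
    return CALIBRATION_INFANT_CAPACITIES


@pytest.fixture(scope="session")
def settings():
    return SimulationSettings()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
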