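import numpy as np
import pytest

from chemosignal import presets
from chemosignal.synthetic import BleachModel, SwitchingModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def symmetric_model():
    """Symmetric two-state switching: stationary CW bias exactly 0.5."""
    return SwitchingModel(rate_ccw_to_cw=0.325, rate_cw_to_ccw=0.325,
                          speed_hz=10.0)


@pytest.fixture
def default_constants():
    return presets.DEFAULT_EFRET_CONSTANTS


@pytest.fixture
def default_schedule():
    return presets.fret_preset()


@pytest.fixture
def no_bleach():
    return BleachModel.none()


@pytest.fixture
def calibration():
    return presets.DEFAULT_RING_CALIBRATION
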