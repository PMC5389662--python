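import numpy as np
import pytest

from milliflow.hydrodynamics import ChannelGeometry, FlowDrive, ROILayout
from milliflow.synthetic import detection_calibration


@pytest.fixture(scope="session")
def square_channel():
    """1 mm x 1 mm channel, the tallest of the five-channel set."""
    return ChannelGeometry.from_um(1000, 1000)


@pytest.fixture(scope="session")
def square_drive(square_channel):
    """1 mL/h at water viscosity."""
    return FlowDrive.from_ml_per_h(square_channel, 1.0)


@pytest.fixture(scope="session")
def shallow_channel():
    """250 um x 1 mm channel, the strongest confinement."""
    return ChannelGeometry.from_um(250, 1000)


@pytest.fixture(scope="session")
def shallow_drive(shallow_channel):
    return FlowDrive.from_ml_per_h(shallow_channel, 1.0)


@pytest.fixture(scope="session")
def layout():
    return ROILayout()


@pytest.fixture(scope="session")
def calibration():
    """Detection calibration matching the generator's saturating response."""
    return detection_calibration()


@pytest.fixture(scope="session")
def dyadic_channel():
    """Exactly-representable square geometry for bit-level symmetry checks."""
    side = 2.0**-10  # ~0.977 mm, dyadic so mirrors are exact in binary
    return ChannelGeometry(side, side)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
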