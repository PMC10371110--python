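import numpy as np
import pytest

from fgskit.optics import CameraModel
from fgskit.scene import (
    IlluminationModel,
    OpticalChannel,
    UniformIllumination,
)


@pytest.fixture(scope="session")
def cam_small() -> CameraModel:
    """Coarsely binned sensor mode: fast to render, same field of view."""
    return CameraModel.rpi_v2(binning=8)


@pytest.fixture(scope="session")
def cam_medium() -> CameraModel:
    return CameraModel.rpi_v2(binning=4)


@pytest.fixture(scope="session")
def flat_ill() -> UniformIllumination:
    return UniformIllumination(level=20.0)


@pytest.fixture(scope="session")
def beam_ill() -> IlluminationModel:
    return IlluminationModel()


@pytest.fixture(scope="session")
def nir_channel() -> OpticalChannel:
    return OpticalChannel.nir("dbl_830lp")


@pytest.fixture(scope="session")
def visible_channel() -> OpticalChannel:
    return OpticalChannel.visible()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
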