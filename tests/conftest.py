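import warnings

import numpy as np
import pytest

from lfaquant.image import RectifiedStrip
from lfaquant.layout import DeviceModel, DoseResponse, Pose, StripLayout

# skimage deprecation chatter is irrelevant to what the tests assert
warnings.filterwarnings("ignore", category=FutureWarning, module="skimage")


@pytest.fixture(scope="session")
def layout() -> StripLayout:
    return StripLayout()


@pytest.fixture(scope="session")
def dr() -> DoseResponse:
    return DoseResponse()


@pytest.fixture(scope="session")
def dr_no_floor() -> DoseResponse:
    return DoseResponse(floor=0.0)


@pytest.fixture(scope="session")
def identity_device() -> DeviceModel:
    return DeviceModel.identity()


@pytest.fixture(scope="session")
def framed_pose(layout) -> Pose:
    return Pose.framed(layout, rotation_deg=7.0, perspective=0.02, scale=0.85)


def as_rectified(img) -> RectifiedStrip:
    """Wrap an identity-pose capture as a canonical rectified strip."""
    from lfaquant._color import srgb_decode

    pixels = img.pixels if img.color_space == "linear" else srgb_decode(img.pixels)
    return RectifiedStrip(pixels, np.eye(3))
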