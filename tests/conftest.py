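import numpy as np
import pytest

from gazealter.gaze_geometry import PixelGazePoint
from gazealter.io_formats import GazeLogRecord, HeadLogRecord


@pytest.fixture
def scene_image():
    """Smooth synthetic scene (uint8 gray) for renderer tests."""
    h = w = 128
    ys, xs = np.mgrid[0:h, 0:w]
    img = 100 + 80 * np.sin(xs / 10.0) + 40 * np.cos(ys / 13.0)
    return np.clip(img, 0, 255).astype(np.uint8)


@pytest.fixture
def scene_rgb(scene_image):
    return np.stack([scene_image, scene_image[::-1], scene_image.T], axis=-1)


@pytest.fixture
def center_gaze(scene_image):
    h, w = scene_image.shape
    return PixelGazePoint(w / 2.0, h / 2.0)


def make_gaze_record(time_s=0.0, eye="left", validity=31, direction=(0.0, 0.0, 1.0),
                     origin=(0.0, 0.0, 60.0), openness=1.0):
    return GazeLogRecord(
        time_s=time_s, eye=eye, validity=validity, openness=openness,
        pupil_diameter_mm=3.5, pupil_position=(0.5, 0.5),
        gaze_origin_mm=origin, gaze_direction_norm=direction,
    )


def make_head_record(time_s=0.0, orientation=(0.0, 0.0, 0.0),
                     position=(0.0, 1.4, 0.0)):
    return HeadLogRecord(time_s=time_s, position_m=position,
                         orientation_deg=orientation)


@pytest.fixture
def gaze_record_factory():
    return make_gaze_record


@pytest.fixture
def head_record_factory():
    return make_head_record
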