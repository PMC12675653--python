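import numpy as np
import pytest

from gazeqc import (
    CameraModel,
    DeviceProfile,
    GazeRecording,
    ParticipantProfile,
    ScreenGeometry,
    TrialSchedule,
    render_scene_frame,
)


def make_rec(x, y, valid=None, **kwargs):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    kwargs.setdefault("timestamps", np.arange(len(x), dtype=float) * 0.01)
    kwargs.setdefault("pupil", np.full(len(x), 3.0))
    return GazeRecording(x=x, y=y, valid=np.asarray(valid, bool), **kwargs)


@pytest.fixture
def recording_factory():
    return make_rec


@pytest.fixture(scope="session")
def camera():
    return CameraModel(fx=1400.0, fy=1400.0, cx=640.0, cy=360.0,
                       width=1280, height=720)


@pytest.fixture(scope="session")
def distorted_camera():
    return CameraModel(fx=1400.0, fy=1400.0, cx=640.0, cy=360.0,
                       distortion=(-0.1, 0.0, 0.0, 0.0, 0.0),
                       width=1280, height=720)


@pytest.fixture(scope="session")
def screen():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def rendered_bright(distorted_camera, screen):
    """One rendered bright frame with distortion, shared across tests."""
    return render_scene_frame(distorted_camera, screen, "bright", (3.0, -2.0),
                              supersample=2)


@pytest.fixture
def quiet_device():
    return DeviceProfile(noise_std=0.0, blink_rate=0.0)


@pytest.fixture
def default_participant():
    return ParticipantProfile()


@pytest.fixture
def schedule():
    return TrialSchedule()
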