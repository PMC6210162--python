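import numpy as np
import pytest

from updrskit.camera import CameraModel
from updrskit.synthetic import (HandRig, MotionParams, embed_in_3d,
                                generate_scalar_profile, render_frames)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_camera():
    return CameraModel(fx=300.0, fy=300.0, cx=160.0, cy=120.0, width=320, height=240)


@pytest.fixture(scope="session")
def rig():
    return HandRig()


@pytest.fixture(scope="session")
def ft_profile():
    """Noise-free 10-cycle finger-tapping profile, A=60 mm, f=2 Hz."""
    params = MotionParams(task="FT", base_amplitude=60.0, base_frequency=2.0,
                          n_cycles=10, seed=0)
    return generate_scalar_profile(params)


@pytest.fixture(scope="session")
def ft_recording(ft_profile):
    return embed_in_3d(ft_profile)


@pytest.fixture(scope="session")
def rendered_sequence(small_camera, rig):
    """Short rendered FT sequence with its source recording."""
    params = MotionParams(task="FT", base_amplitude=60.0, base_frequency=2.0,
                          n_cycles=4, baseline=20.0, seed=3)
    rec = embed_in_3d(generate_scalar_profile(params), rig)
    frames = list(render_frames(rec, rig, small_camera))
    return rec, frames
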