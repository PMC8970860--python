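import numpy as np
import pytest

from strabmetric import (EyeParams, JitterSpec, default_subject,
                         make_eye_scene, make_nine_gaze_set,
                         simulate_palsy_preset)


@pytest.fixture(scope="session")
def small_shape():
    return (240, 360)


@pytest.fixture(scope="session")
def small_eyes(small_shape):
    """Two r=20 limbus eyes that fit a small frame, left eye at (100, 120)."""
    left = EyeParams(20.0, (100.0, 120.0), (0.0, 0.0), reflex_point=(100.0, 120.0))
    right = EyeParams(20.0, (260.0, 120.0), (0.0, 0.0), reflex_point=(260.0, 120.0))
    return left, right


@pytest.fixture(scope="session")
def primary_scene(small_eyes, small_shape):
    return make_eye_scene(small_eyes, small_shape)


@pytest.fixture(scope="session")
def subject_512():
    return default_subject((512, 512))


@pytest.fixture(scope="session")
def normal_set_512(subject_512):
    """Nine-gaze set with symmetric 32-px excursions and no jitter."""
    spec = simulate_palsy_preset("CN6_left", excursion_px=32.0, ratio=1.0)
    return make_nine_gaze_set(subject_512, spec, jitter_spec=None,
                              image_shape=(512, 512))


@pytest.fixture(scope="session")
def jittered_set_512(subject_512):
    spec = simulate_palsy_preset("CN6_left", excursion_px=32.0, ratio=1.0)
    return make_nine_gaze_set(subject_512, spec, jitter_spec=JitterSpec(),
                              seed=7, image_shape=(512, 512))


@pytest.fixture
def rng():
    return np.random.default_rng(20220324)
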