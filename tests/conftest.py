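import numpy as np
import pytest

from ficaread import CameraModel, build_scene, capture


@pytest.fixture
def noisy_camera():
    """Default study camera: reference sensor line, 1-gray read noise,
    sparse impulse noise, fixed seed."""
    return CameraModel(read_noise_sigma=1.0, impulse_noise_prob=0.002, rng_seed=1)


@pytest.fixture
def noiseless_camera():
    return CameraModel(rng_seed=0)


@pytest.fixture
def strip_image(noisy_camera):
    """A mid-range strip capture (31.25 ug/mL at the 100 ms reference
    exposure) used by segmentation/quantification tests."""
    return capture(build_scene(31.25), noisy_camera, 100.0)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return 1.0 if union == 0 else (a & b).sum() / union
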