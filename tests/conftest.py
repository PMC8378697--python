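import numpy as np
import pytest

from gazekit.camera import CameraModel
from gazekit.io_sync import load_session
from gazekit.synthetic import searching_config, simulate_session, walking_config


@pytest.fixture
def camera() -> CameraModel:
    return CameraModel(
        image_width_px=640,
        image_height_px=480,
        horizontal_fov_deg=111.0,
        distortion=(-0.05, 0.01),
    )


@pytest.fixture(scope="session")
def walk_bundle(tmp_path_factory):
    """One rendered walking session bundle plus its ground truth."""
    out = tmp_path_factory.mktemp("walk_session")
    path, truth = simulate_session(walking_config(seed=7), out)
    return path, truth


@pytest.fixture(scope="session")
def search_bundle(tmp_path_factory):
    """One rendered searching session bundle plus its ground truth."""
    out = tmp_path_factory.mktemp("search_session")
    path, truth = simulate_session(searching_config(seed=7), out)
    return path, truth


@pytest.fixture(scope="session")
def walk_session(walk_bundle):
    path, truth = walk_bundle
    return load_session(path), truth
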