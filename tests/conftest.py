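import numpy as np
import pytest

from facekit import io_core, synthdata as sd


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def schema():
    return io_core.default_schema()


@pytest.fixture(scope="session")
def ou_series():
    """Multi-timescale OU keypoint traces, 10 min at 50 Hz (session-cached)."""
    return sd.make_keypoint_traces(30000, rate=50.0, seed=7)


@pytest.fixture(scope="session")
def small_scene():
    """3-keypoint blob scene at 128 px."""
    return sd.FaceSceneSpec(image_size=128, seed=0)
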