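import numpy as np
import pytest

from spinafi.dff import FluorescenceStack
from spinafi.simulate import SceneParams


@pytest.fixture
def rng():
    return np.random.default_rng(20140923)


def make_stack(rng, n_frames=6, shape=(4, 4), onset=2.0, lo=100, hi=60000):
    """Random integer stack with frame interval 1 s and onset after frame 1."""
    frames = rng.integers(lo, hi, size=(n_frames, *shape))
    return FluorescenceStack(
        frames=frames,
        frame_times=np.arange(n_frames, dtype=float),
        stim_onset=onset,
        stim_offset=onset + 1.0,
    )


@pytest.fixture
def stack_factory(rng):
    def factory(**kwargs):
        return make_stack(rng, **kwargs)

    return factory


@pytest.fixture
def default_scene():
    return SceneParams()


@pytest.fixture
def noiseless_scene():
    return SceneParams(noise_scale=0.0)


@pytest.fixture
def tiny_scene():
    """Reduced problem size for multi-replicate pipeline runs."""
    return SceneParams(shape=(32, 32), duration_s=12.0, stim_onset_s=2.0, frame_rate_hz=5.0)
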