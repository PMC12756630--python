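import numpy as np
import pytest

from exotrack.synthetic import NoiseMix, random_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_scene():
    """A distinct-geometry 128×128 scene with no noise mixed in."""
    return random_scene(
        (128, 128), 8, (3, 6), np.random.default_rng(42),
        noise=NoiseMix(w1=0.0, w2=0.0, seed=42),
    )


@pytest.fixture
def noisy_scene():
    """The default study condition: distinct circles, w1 = w2 = 0.2."""
    return random_scene(
        (128, 128), 10, (3, 6), np.random.default_rng(7),
        noise=NoiseMix(w1=0.2, w2=0.2, seed=7),
    )
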