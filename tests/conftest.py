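import numpy as np
import pytest

from mitoprox import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_mask_pair(rng):
    """One dense-ish random 64x64 mask pair."""
    a = rng.random((64, 64)) < 0.3
    b = rng.random((64, 64)) < 0.3
    return a, b


@pytest.fixture(scope="session")
def noiseless_scene():
    """Noiseless network scene with a membrane-localized protein."""
    return generate_scene(SceneConfig(seed=5, noise_scale=0.0, protein_mode="membrane"))


@pytest.fixture(scope="session")
def noisy_scene():
    """Default (noisy) network scene with partial colocalization."""
    return generate_scene(SceneConfig(seed=5))
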