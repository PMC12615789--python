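import numpy as np
import pytest

from forestmap.synthetic import LayoutConfig, generate_scene


@pytest.fixture(scope="session")
def noiseless_scene():
    """A 64-px scene whose label sources exactly equal the truth maps."""
    layout = LayoutConfig(size=64, noise_sigma=0.0, source_fp=0.0, source_fn=0.0)
    return generate_scene(seed=7, layout=layout)


@pytest.fixture(scope="session")
def noisy_scene():
    return generate_scene(seed=11, layout=LayoutConfig(size=64))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
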