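import numpy as np
import pytest

import myofind as mf


@pytest.fixture(scope="session")
def small_phantom():
    """A modest beating-cell phantom shared across detection tests."""
    spec = mf.PhantomSpec(image_size=(768, 768), n_cells=2, seed=11,
                          beat_fraction=1.0)
    stack, truth = mf.generate_video(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def mixed_phantom():
    """Three cells, mixed beating/static, default conditions."""
    spec = mf.PhantomSpec(n_cells=3, seed=7, beat_fraction=0.5)
    stack, truth = mf.generate_video(spec)
    return spec, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
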