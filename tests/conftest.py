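import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cystseg as cs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_level_phantom():
    """Noise-free, blur-free two-level phantom: every stage is exact."""
    spec = cs.PhantomSpec(
        background_level=150.0,
        cyst_level=60.0,
        ellipses=(cs.Ellipse(120.0, 130.0, 35.0, 25.0, 0.4),),
        border_sigma=0.0,
        speckle_scale=0.0,
        seed=7,
    )
    img, truth = cs.generate_phantom(spec)
    return img, truth


@pytest.fixture
def easy_phantom():
    img, truth, _ = cs.generate_suite(1, "easy", seed=5)[0]
    return img, truth
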