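import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import soilcarbon as sc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def params():
    return sc.DecompositionParams.modified()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_params_factory():
    """Draw valid random parameter sets spanning fast to slow kinetics."""

    def make(rng):
        return sc.DecompositionParams(
            k_labile=rng.uniform(1e-3, 5e-2),
            k_resistant=rng.uniform(1e-4, 5e-3),
            k_light=rng.uniform(5e-5, 1e-3),
            k_heavy=rng.uniform(5e-6, 1e-4),
            f_labile_light=rng.uniform(0.0, 1.0),
            f_resistant_light=rng.uniform(0.0, 1.0),
            f_light_heavy=rng.uniform(0.0, 1.0),
        )

    return make
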