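import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_plate():
    """4 ZZ + 4 Z0 animals, zero replicate noise, shared input offsets."""
    from zdose.simulate import SimConfig, simulate_cohort

    config = SimConfig(
        n_male=4, n_female=4, noise_sd=0.0, sample_offset_sd=0.5, seed=11
    )
    return simulate_cohort(config)
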