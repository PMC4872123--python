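import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from numind import EngineParams, run_experiment, run_many  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def zero_act_params():
    """Deterministic engine with every activation at 0 (all retrievals 0.4 s),
    for hand-computable critical paths."""
    p = EngineParams(activation_noise_sd=0.0)
    p.activation = {k: 0.0 for k in p.activation}
    return p


@pytest.fixture(scope="session")
def default_experiment():
    return run_experiment(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten model runs at default parameters, shared across read-only tests."""
    return run_many(10, seed=5)
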