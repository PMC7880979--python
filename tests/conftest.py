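import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def target_grid():
    from driftspec.synthetic import build_target_grid

    return build_target_grid()


@pytest.fixture(scope="session")
def protocol(target_grid):
    from driftspec.synthetic import build_presentation_sequence

    return build_presentation_sequence(target_grid, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
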