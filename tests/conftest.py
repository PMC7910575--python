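import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def receiver_grid_14():
    from fishssm.fixtures import make_receiver_grid

    return make_receiver_grid(14, 150.0)


@pytest.fixture(scope="session")
def study_transition():
    """Stay-heavy transition regime consistent with resident-fish fits."""
    from fishssm.behaviour import TransitionParams

    return TransitionParams.from_probs(
        {
            "p_day_noise": 0.95,
            "q_day_noise": 0.85,
            "p_day_silence": 0.95,
            "q_day_silence": 0.85,
            "p_night_noise": 0.75,
            "q_night_noise": 0.95,
            "p_night_silence": 0.75,
            "q_night_silence": 0.95,
        }
    )
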