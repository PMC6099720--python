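import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def sharp_pwm():
    """Width-8 near-deterministic PWM; consensus ACGTACGT."""
    from atacmd.scanner import PWM

    matrix = np.full((8, 4), 0.01)
    matrix[np.arange(8), [0, 1, 2, 3, 0, 1, 2, 3]] = 0.97
    return PWM.from_probabilities("SHARP", matrix / matrix.sum(1, keepdims=True))


@pytest.fixture
def palindromic_pwm():
    """Width-4 PWM whose consensus ACGT equals its own reverse complement."""
    from atacmd.scanner import PWM

    matrix = np.full((4, 4), 0.02)
    matrix[np.arange(4), [0, 1, 2, 3]] = 0.94
    return PWM.from_probabilities("PALIN", matrix / matrix.sum(1, keepdims=True))


def random_sequence(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
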