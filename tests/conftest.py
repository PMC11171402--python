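import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ethochain import (
    BehaviorState,
    Ethogram,
    Stage,
    vannamei_ethogram,
    vannamei_transition_matrix,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def eth():
    return vannamei_ethogram()


@pytest.fixture(scope="session")
def matrix():
    return vannamei_transition_matrix()


@pytest.fixture(scope="session")
def tiny_eth():
    """Three-state toy ethogram with a 2+1 stage split."""
    states = (
        BehaviorState("a", "A", 0),
        BehaviorState("b", "B", 1),
        BehaviorState("c", "C", 2),
    )
    stages = (Stage("active", ("a", "b")), Stage("passive", ("c",)))
    return Ethogram(states, stages, name="toy")


def random_stochastic(n: int, rng: np.random.Generator, no_self: bool = False) -> np.ndarray:
    """Random row-stochastic matrix (optionally zero diagonal)."""
    p = rng.random((n, n)) + 0.05
    if no_self:
        np.fill_diagonal(p, 0.0)
    return p / p.sum(axis=1, keepdims=True)
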