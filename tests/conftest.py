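import numpy as np
import pytest

from cdmst.gdina import (
    GDINAItem,
    ItemFeatures,
    simulate_item_bank,
    simulate_knowledge_states,
    simulate_responses,
)
from cdmst.study import generate_fixture


@pytest.fixture(scope="session")
def tiny():
    """Miniature K=3 fixture: 60-item bank, 100 examinees, 1-panel spec."""
    return generate_fixture(3, "tiny")


@pytest.fixture(scope="session")
def small_bank():
    """An 80-item K=3 bank with features, for assembly/evaluation tests."""
    return simulate_item_bank(80, 3, np.random.default_rng(42), enemy_fraction=0.05)


@pytest.fixture(scope="session")
def small_sample(small_bank):
    """(states, responses) of 200 examinees on the small bank."""
    rng = np.random.default_rng(7)
    states = simulate_knowledge_states(200, small_bank.K, rng)
    return states, simulate_responses(small_bank, states, rng)


@pytest.fixture
def dina_like_item():
    """q=(1,1,0,0,0), P=0.2 unless both measured attributes mastered (0.9)."""
    return GDINAItem(
        0,
        np.array([1, 1, 0, 0, 0]),
        np.array([0.2, 0.2, 0.2, 0.9]),
        ItemFeatures(1, 1, 1),
    )
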