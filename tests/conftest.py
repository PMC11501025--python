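import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

import bindmode as bm


@pytest.fixture(scope="session")
def tiny_space() -> bm.SequenceSpace:
    """16-sequence space over a 4-letter alphabet: everything is enumerable."""
    return bm.SequenceSpace(alphabet="ACDE", length=2)


@pytest.fixture(scope="session")
def tiny_campaign(tiny_space):
    """A small two-round campaign with known truth on the 16-sequence space."""
    config = bm.SimulationConfig(
        length=2, alphabet="ACDE", depth=5000, seed=11, absent_fraction=0.25
    )
    return bm.simulate_campaign(config)


@pytest.fixture(scope="session")
def small_campaign():
    """A 400-sequence campaign (20-letter alphabet, length 2) at modest depth."""
    config = bm.SimulationConfig(length=2, depth=50_000, seed=5)
    return bm.simulate_campaign(config)


@pytest.fixture(scope="session")
def small_fit(small_campaign):
    """One shared fit of the small campaign (independent-site, full batch)."""
    state, report = bm.fit(
        small_campaign.graph,
        small_campaign.counts,
        small_campaign.space,
        bm.FitConfig(epochs=150, batch_size=None, learning_rate=0.05, seed=0),
    )
    return state, report


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
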