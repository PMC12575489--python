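import numpy as np
import pytest

from hhtf import (ImpactScenario, resample, simulate_session)
from hhtf.pipeline import pair_impacts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def front_session():
    """Small paired front-impact session shared by detection/direction/transfer tests."""
    sc = ImpactScenario(location="front", energy_j=33.0, n_trials=4,
                        gap_s=2.0, seed=7)
    helmet, headform, truth = simulate_session(sc)
    return sc, helmet, headform, truth


@pytest.fixture(scope="session")
def front_pairs(front_session):
    sc, helmet, headform, truth = front_session
    return pair_impacts(helmet, headform, truth, location=sc.location,
                        energy_j=sc.energy_j)
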