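import numpy as np
import pytest

from crossnum.behavior_sim import PopulationParams, simulate_behavior


@pytest.fixture(scope="session")
def default_sim():
    """One simulated behavioral cohort at the default study conditions."""
    return simulate_behavior(PopulationParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
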