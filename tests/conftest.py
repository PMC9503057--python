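import dataclasses

import numpy as np
import pytest

from ringclim import SyntheticScenario, simulate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """Reduced study scenario: 12 trees per class, shorter series."""
    return SyntheticScenario(n_trees=12, length_range=(60, 90), seed=42)


@pytest.fixture(scope="session")
def small_data(small_scenario):
    """One simulated data set shared by the integration tests."""
    dataset, trees, reflectance, climate, truth = simulate_scenario(small_scenario)
    return {
        "dataset": dataset,
        "trees": trees,
        "reflectance": reflectance,
        "climate": climate,
        "truth": truth,
        "scenario": small_scenario,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_scenario():
    return SyntheticScenario(seed=7)


def replace(obj, **kw):
    return dataclasses.replace(obj, **kw)
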