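"""Shared fixtures: small simulated datasets and cached fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fishgrowth import (
    GrowthDataset,
    GrowthModel,
    ModelSpec,
    SimulationConfig,
    generate,
)


@pytest.fixture(scope="session")
def single_pop_data():
    """One population, ~165 fish, sparse trajectories, 5 mm error."""
    cfg = SimulationConfig(
        populations={"P1": "MT"},
        fish_per_population=200,
        tag_threshold_mm=None,
        seed=42,
    )
    data, truth = generate(cfg)
    return data, truth, cfg


@pytest.fixture(scope="session")
def single_pop_fit(single_pop_data):
    data, truth, cfg = single_pop_data
    res = GrowthModel(data, ModelSpec()).fit()
    assert res.converged
    return res


@pytest.fixture(scope="session")
def multi_pop_data():
    """Four populations / three species, low noise, dense captures."""
    cfg = SimulationConfig(
        fish_per_population=40,
        tag_threshold_mm=None,
        sigma_eps=3.0,
        capture_prob=0.85,
        seed=7,
    )
    data, truth = generate(cfg)
    return data, truth, cfg


def toy_frame():
    """Three fish, hand-written records."""
    return pd.DataFrame(
        {
            "fish_id": ["a", "a", "b", "b", "b", "c"],
            "species": ["MT", "MT", "MT", "MT", "MT", "BT"],
            "population": ["p1", "p1", "p1", "p1", "p1", "p2"],
            "cohort": [2004, 2004, 2005, 2005, 2005, 2004],
            "age": [1.0, 2.0, 1.0, 2.0, 3.0, 2.0],
            "length": [110.0, 160.0, 95.0, 150.0, 185.0, 120.0],
        }
    )


@pytest.fixture
def toy_data():
    return GrowthDataset(toy_frame())
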