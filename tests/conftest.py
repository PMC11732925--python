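import numpy as np
import pytest

import thresholdage as ta


@pytest.fixture(scope="session")
def molar_truth():
    """Third-molar generative truth (CR-logit non-parallel, uniform ages)."""
    return ta.preset_truth("third_molar", "male", n=4000, seed=11)


@pytest.fixture(scope="session")
def molar_pop(molar_truth):
    return ta.generate_population(molar_truth)


@pytest.fixture(scope="session")
def molar_model(molar_truth, molar_pop):
    """One fitted third-molar model shared across read-only tests."""
    return ta.fit(molar_truth.model.spec, molar_pop)


@pytest.fixture(scope="session")
def molar_support():
    return ta.default_support("third_molar", "male")


@pytest.fixture
def tiny_pop():
    obs = tuple(
        ta.StagedObservation(f"s{i}", "male", "third_molar", stage, age)
        for i, (stage, age) in enumerate(
            [("D", 13.2), ("E", 15.1), ("F", 16.9), ("E", 14.4), ("G", 18.5)]
        )
    )
    return ta.Population(obs, provenance="fixture")
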