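import warnings

import numpy as np
import pytest

from combocox import PathConfig, SurvivalDataset, generate, interaction_demo_spec

from .oracles import random_fixture


@pytest.fixture(autouse=True)
def _quiet_runtime_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def small_fixture() -> SurvivalDataset:
    return random_fixture(3, n=40, m=8)


@pytest.fixture
def tied_fixture() -> SurvivalDataset:
    """A dataset with genuinely tied event times (integer grid)."""
    rng = np.random.default_rng(11)
    n = 30
    items = (rng.random((n, 5)) < 0.4).astype(np.uint8)
    time = rng.integers(1, 8, size=n).astype(float)
    event = (rng.random(n) < 0.7).astype(int)
    event[:2] = 1
    return SurvivalDataset(items=items, time=time, event=event,
                           item_names=[f"i{j}" for j in range(5)])


@pytest.fixture(scope="session")
def demo_cohort():
    """One planted-interaction cohort shared by the slower tests."""
    return generate(interaction_demo_spec(seed=0))


@pytest.fixture
def oracle_path_config() -> PathConfig:
    return PathConfig(max_order=3, max_active=8, lambda_min_ratio=0.05,
                      max_events=30)
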