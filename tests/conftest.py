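import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from mpptree import (
    ItemParams,
    LatentTraits,
    decompose,
    draw_item_params,
    draw_thetas,
    simulate_responses,
)


@pytest.fixture(scope="session")
def small_params() -> ItemParams:
    return draw_item_params(5, seed=42)


@pytest.fixture(scope="session")
def small_traits() -> LatentTraits:
    return draw_thetas(50, seed=43)


@pytest.fixture(scope="session")
def small_likert(small_params, small_traits):
    return simulate_responses(small_params, small_traits, seed=44)


@pytest.fixture(scope="session")
def small_codes(small_likert):
    return decompose(small_likert)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
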