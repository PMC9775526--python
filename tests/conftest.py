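import numpy as np
import pytest

from sleepgan.fixtures import FixtureSpec, generate_fixture_set


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(n_per_stage=8, seed=42)


@pytest.fixture(scope="session")
def fixture_set(small_spec):
    """Eight epochs per stage, shared across the suite."""
    return generate_fixture_set(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
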