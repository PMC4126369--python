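import numpy as np
import pytest

from gdtpoly import simulator


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def canonical():
    return simulator.canonical_pedigree()


@pytest.fixture(scope="session")
def small_sim():
    """A small ascertained sample shared by read-only tests."""
    return simulator.simulate_sample(
        simulator.Scenario(), 40, np.random.default_rng(42)
    )
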