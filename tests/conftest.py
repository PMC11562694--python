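import pytest

from neoprio import SimulationConfig, Thresholds, simulate_cohort


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimulationConfig(seed=11, n_variants=12))


@pytest.fixture(scope="session")
def planted_cohort():
    """The 100-variant cohort used for planted-truth recovery."""
    return simulate_cohort(SimulationConfig(seed=42, n_variants=100))
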