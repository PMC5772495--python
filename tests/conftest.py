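import pytest

from somaburden.datasets import dot1l_like_annovar_table, dot1l_like_missense_table
from somaburden.synthetic_data import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def annovar_table():
    return dot1l_like_annovar_table()


@pytest.fixture(scope="session")
def missense_table():
    return dot1l_like_missense_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with ground truth, shared across tests."""
    config = SyntheticConfig(G=60, S=120, noise_rate=1.5, seed=20240917)
    records, truth = simulate_cohort(config)
    return config, records, truth
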