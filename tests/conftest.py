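import numpy as np
import pytest

from cardiosleep.pipeline import segment_cohort
from cardiosleep.synthetic import simulate_cohort
from cardiosleep.types import SimConfig


@pytest.fixture(scope="session")
def tiny_cohort():
    """Eight short (1 h) subjects spanning all severity strata."""
    return simulate_cohort(
        8, seed=11, base_config=SimConfig(tib_hours=1.0, ahi_target=20.0)
    )


@pytest.fixture(scope="session")
def tiny_store(tiny_cohort):
    return segment_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def one_record():
    return simulate_cohort(4, seed=5, base_config=SimConfig(tib_hours=1.5))[2]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
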