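import numpy as np
import pandas as pd
import pytest

from hpds.simulate import SimConfig, simulate_cohort
from hpds.taxonomy import aggregate_group_intake, default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def small_cohort(taxonomy):
    """Simulated 800-person cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n=800, seed=101), taxonomy)


@pytest.fixture(scope="session")
def small_matrix(small_cohort, taxonomy):
    return aggregate_group_intake(small_cohort.recalls, taxonomy)


def random_intake_matrix(rng, n, taxonomy, zero_frac=0.4):
    """Zero-inflated nonnegative participant x group matrix."""
    g = len(taxonomy.group_ids)
    values = rng.lognormal(3.0, 1.2, size=(n, g))
    values[rng.random((n, g)) < zero_frac] = 0.0
    return pd.DataFrame(values, columns=taxonomy.group_ids,
                        index=[f"P{i}" for i in range(n)])
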