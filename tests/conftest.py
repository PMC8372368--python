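import pytest

from amldecouple.pipeline import preprocess_counts
from amldecouple.simulate import SimulationConfig, simulate_cohort


def small_config(**overrides) -> SimulationConfig:
    """Desk-scale cohort: full sample size, reduced gene universe."""
    base = dict(n_samples=81, n_genes=3000, n_lineage_genes=200, seed=1)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def log2_matrix(cohort):
    return preprocess_counts(cohort.expression)
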