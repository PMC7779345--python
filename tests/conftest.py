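import warnings

import pytest

from dabble import (
    DecompositionConfig,
    GValueSimSpec,
    SurvivalSimSpec,
    generate_gvalue_table,
    generate_survival_counts,
)


@pytest.fixture(scope="session")
def gsim_spec():
    return GValueSimSpec()


@pytest.fixture(scope="session")
def gtable(gsim_spec):
    return generate_gvalue_table(gsim_spec)


@pytest.fixture(scope="session")
def sim_spec():
    """The canonical fixed-seed synthetic suite: 10 LETs, 3 replicates, 500 cells."""
    return SurvivalSimSpec(seed=0)


@pytest.fixture(scope="session")
def sim(sim_spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return generate_survival_counts(sim_spec)


@pytest.fixture(scope="session")
def config():
    return DecompositionConfig()
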