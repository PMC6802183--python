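import numpy as np
import pytest

from hypoxsim.builtin import (
    RATIO_MAPPING,
    builtin_model,
    load_hif_network,
    load_tumor_network,
)
from hypoxsim.network_model import Environment
from hypoxsim.population import (
    EnsembleConfig,
    generate_population,
    simulate_conditions,
    toy_fixture_network,
)

#: hypoxia step levels used throughout (fractions of normoxia)
O2_LEVELS = (0.05, 0.005, 0.001)


@pytest.fixture(scope="session")
def model():
    return builtin_model()


@pytest.fixture(scope="session")
def hif_network():
    return load_hif_network()


@pytest.fixture(scope="session")
def tumor_network():
    return load_tumor_network()


@pytest.fixture()
def linear_chain():
    return toy_fixture_network("linear_chain")


@pytest.fixture()
def phospho_cycle():
    return toy_fixture_network("phospho_cycle")


@pytest.fixture()
def vegf_loop():
    return toy_fixture_network("vegf_loop")


@pytest.fixture(scope="session")
def study(model):
    """Scaled-down virtual-population study shared by the heavier tests.

    300 virtual cells equilibrated at normoxia, stepped to 5%, 0.5% and
    0.1% O2.  Smaller than the full 20,000-case study but large enough for
    stable category fractions and tree roots.
    """
    records = generate_population(model, EnsembleConfig(n_cases=300, seed=11))
    conds = [Environment(o2_fraction=f) for f in O2_LEVELS]
    simulate_conditions(model, records, conds)
    return {"records": records, "conditions": dict(zip(O2_LEVELS, conds))}
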