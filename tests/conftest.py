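import logging

import pytest

from ipvkit import synthetic
from ipvkit.registry import default_registry

# negative-cd floor warnings are expected on the reference WBCF rows and
# would otherwise flood the test log
logging.getLogger("ipvkit.ipv").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def population():
    return synthetic.default_flourishing_population()


@pytest.fixture(scope="session")
def responses_698(population):
    """One study-sized discretized sample, shared across tests."""
    data, truth = synthetic.simulate_responses(population, n=698, seed=20240698)
    return data, truth


@pytest.fixture(scope="session")
def nested_698(responses_698, registry):
    """Nested IPV result on the study-sized sample (fit once per session)."""
    from ipvkit import ipv
    from ipvkit.registry import validate_responses

    data, _ = responses_698
    return ipv.run_nested_ipv(validate_responses(data, registry), registry)


@pytest.fixture(scope="session")
def continuous_5000(population):
    """Continuous (undiscretized) sample for parameter-recovery checks."""
    data, _ = synthetic.simulate_responses(
        population, n=5000, seed=50001, continuous=True, ground_truth=False
    )
    return data
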