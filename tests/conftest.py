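import pytest
from hypothesis import HealthCheck, settings

import fluxcompare as fc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def chain_model():
    return fc.fixtures.make_chain(k=3, uptake=10.0)


@pytest.fixture
def branch_model():
    return fc.fixtures.make_branch(uptake=10.0, m=2)


@pytest.fixture
def two_nutrient():
    return fc.fixtures.make_two_nutrient()


@pytest.fixture
def random_models():
    return [
        fc.fixtures.make_random_network(seed, n_reactions=6, n_metabolites=3)
        for seed in range(20)
    ]
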