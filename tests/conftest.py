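import pytest
from hypothesis import HealthCheck, settings

from anca.fixtures import make_peptide, make_toy_energy_table
from helpers import annotated

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def helix_model():
    return annotated(make_peptide("helix_peptide", 12))


@pytest.fixture
def toy_table():
    return make_toy_energy_table(7)


@pytest.fixture
def negative_table():
    return make_toy_energy_table(7, negative_only=True)
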