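import pytest
from hypothesis import HealthCheck, settings

from ergokinetics import EnergeticsParameters, LactateParameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    """Published default athlete/model constants."""
    return EnergeticsParameters()


@pytest.fixture(scope="session")
def lpar():
    """Published default lactate-model constants."""
    return LactateParameters()
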