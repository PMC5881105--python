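import pytest
from hypothesis import HealthCheck, settings

from aippred import synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def strong_data():
    """120 peptides with strong planted class structure."""
    return synthetic.generate(
        60, 60, synthetic.get_profile("figure1_strong"), seed=11
    )


@pytest.fixture(scope="session")
def null_data():
    """120 peptides with identical class profiles (no signal)."""
    return synthetic.generate(60, 60, synthetic.get_profile("null"), seed=12)


@pytest.fixture(scope="session")
def small_grid():
    return {"ntree": (50,), "mtry": (1, 2), "nsplit": (2,)}
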