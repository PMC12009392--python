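import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=200,
    derandomize=True,
    deadline=None,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def hp_small():
    """A small, fast hyper-parameter set for structural unit tests."""
    from nalseq import HyperParams

    return HyperParams(n_c=5, xi=6)


@pytest.fixture
def network(hp_small):
    from nalseq import ConceptNetwork

    return ConceptNetwork(hp_small)
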