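import pytest
from hypothesis import HealthCheck, settings

from hhpair import NeuronParams, NeuronState, PulseStimulus, TimeGrid

# deterministic hypothesis runs, no example database on disk
settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> NeuronParams:
    """The classical squid-axon parameter set."""
    return NeuronParams()


@pytest.fixture(scope="session")
def case2() -> NeuronState:
    """Initial state at the self-consistent resting gates."""
    return NeuronState(-65.0, 0.0529, 0.5961, 0.3177)


@pytest.fixture(scope="session")
def standard_pulse():
    """The reference 100 uA/cm^2 x 2 ms pulse, onset 4 ms."""
    return PulseStimulus(amplitude=100.0, onset=4.0, width=2.0)


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid(0.0, 50.0, 0.01)
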