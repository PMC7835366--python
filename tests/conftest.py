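import numpy as np
import pytest
from hypothesis import settings

from spikepattern import GeneratorSpec, SpikeTrain, generate_train

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def periodic_train():
    """Perfectly periodic 2 Hz train, 500 s (1000 spikes)."""
    ts = np.arange(1000) * 0.5
    return SpikeTrain("periodic-2hz", ts, 500.0)


@pytest.fixture(scope="session")
def poisson_train():
    """Exponential-ISI (Poisson) train at 3 Hz, 600 s."""
    spec = GeneratorSpec(pattern="irregular", rate=3.0, duration=600.0,
                         shape=1.0, seed=42)
    return generate_train(spec)


@pytest.fixture(scope="session")
def regular_train():
    return generate_train(
        GeneratorSpec(pattern="regular", rate=3.3, duration=300.0, seed=7),
        min_spikes=600,
    )


@pytest.fixture(scope="session")
def irregular_train():
    return generate_train(
        GeneratorSpec(pattern="irregular", rate=3.3, duration=300.0, seed=7),
        min_spikes=600,
    )


@pytest.fixture(scope="session")
def bursty_train():
    return generate_train(
        GeneratorSpec(pattern="bursty", rate=3.5, duration=300.0, seed=7),
        min_spikes=600,
    )
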