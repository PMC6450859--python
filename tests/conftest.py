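import numpy as np
import pytest

from clamptrace import ClampProtocol, Group, Subject
from clamptrace.simulator import NoiseModel, SimulationTruth, simulate_subject


@pytest.fixture(scope="session")
def protocol() -> ClampProtocol:
    return ClampProtocol()


@pytest.fixture(scope="session")
def subject() -> Subject:
    return Subject("S001", Group.BAM, weight_kg=90.0, height_cm=175.0,
                   vat_kg=4.0, sat_kg=12.0, muscle_kg=20.0)


@pytest.fixture(scope="session")
def noisefree_sim(subject, protocol):
    """One noise-free simulated clamp with mid-range physiology."""
    return simulate_subject(
        subject, protocol, truth=SimulationTruth(seed=11), noise=NoiseModel.none()
    )


@pytest.fixture(scope="session")
def noisy_sim(subject, protocol):
    """Same subject at the default measurement noise."""
    return simulate_subject(
        subject, protocol, truth=SimulationTruth(seed=11), noise=NoiseModel(),
        rng=np.random.default_rng(23),
    )
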