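import numpy as np
import pytest

from neurolfp import (
    CurrentInjection,
    Medium,
    Point3,
    SegmentSource,
    StimulusProtocol,
    make_demo_neuron,
    simulate,
)


@pytest.fixture(scope="session")
def medium():
    return Medium()


@pytest.fixture(scope="session")
def granule_segment():
    """A granule-scale line source: 10 um long, 1 um diameter, along x."""
    return SegmentSource("seg", Point3(0, 0, 0), Point3(10, 0, 0), 1.0)


@pytest.fixture(scope="session")
def injected_cell():
    """Ball-and-stick cell under a somatic current step (non-conserving sum)."""
    model = make_demo_neuron("ball_and_stick", seed=0)
    proto = StimulusProtocol(injections=[CurrentInjection("soma", 150.0, 5.0, 40.0)])
    return simulate(model, proto, t_stop=60.0, seed=0)


@pytest.fixture(scope="session")
def synaptic_cell():
    """Ball-and-stick cell driven synaptically: currents sum to zero each step."""
    model = make_demo_neuron("ball_and_stick", seed=0)
    proto = StimulusProtocol(spike_trains={0: [10.0, 25.0, 40.0]})
    return simulate(model, proto, t_stop=60.0, seed=0)


def biphasic_current(n_steps: int = 200, dt: float = 0.025) -> np.ndarray:
    """A spike-like biphasic waveform (nA): brief inward then outward phase."""
    t = np.arange(n_steps) * dt
    wave = -1.2 * np.exp(-((t - 1.0) ** 2) / (2 * 0.15**2))
    wave += 0.8 * np.exp(-((t - 1.8) ** 2) / (2 * 0.35**2))
    return wave
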