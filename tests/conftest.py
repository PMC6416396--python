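"""Shared fixtures: small simulated worlds and canonical traces."""

import numpy as np
import pytest

from pafocus.forward_sim import (
    AbsorberSpec,
    TransducerSpec,
    make_default_world,
    synthesize_waveform,
)
from pafocus.correlation_gate import initial_template


@pytest.fixture(scope="session")
def default_world():
    """The full-size default study world (576 segments, 7 modes)."""
    return make_default_world(seed=0)


@pytest.fixture(scope="session")
def default_template(default_world):
    return initial_template(default_world, seed=0)


@pytest.fixture(scope="session")
def small_quiet_world():
    """A small noise-free world for fast deterministic checks."""
    return make_default_world(
        seed=1, n_segments=16, m_modes=2, sigma=0.0, clutter_rate=0.0
    )


@pytest.fixture(scope="session")
def absorber():
    return AbsorberSpec(grueneisen=0.2, mu_a=5.0, diameter=150e-6, arrival_time=5e-6)


@pytest.fixture(scope="session")
def transducer():
    return TransducerSpec(center_freq=5e6, fractional_bandwidth=0.8)


@pytest.fixture(scope="session")
def clean_pulse(absorber, transducer):
    """Unit-amplitude 6.6 MHz pulse, 2048 samples at 5 ns."""
    return synthesize_waveform(1.0, absorber, transducer, 1500.0, 5e-9, 2048)
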