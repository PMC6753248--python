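import numpy as np
import pytest

from speechimagery.network import NetworkParams, NetworkTopology
from speechimagery.synth import SynthConfig, synth_behavior


@pytest.fixture(scope="session")
def params():
    return NetworkParams()


@pytest.fixture(scope="session")
def topology():
    return NetworkTopology()


@pytest.fixture(scope="session")
def small_dataset():
    """Six-participant synthetic dataset shared by the statistics tests."""
    return synth_behavior(SynthConfig(n_participants=6, seed=42))


@pytest.fixture(scope="session")
def default_dataset():
    """Full-design synthetic dataset (19 participants)."""
    return synth_behavior(SynthConfig(seed=7))
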