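import numpy as np
import pytest

from spikesampling.calibration import calibrate
from spikesampling.chain_coupling import SAMPLING_NEURON
from spikesampling.graph_model import BayesianNetwork


@pytest.fixture(scope="session")
def std_calib():
    """Standard-profile calibration shared across LIF tests."""
    return calibrate(duration=50000.0, free_duration=10000.0, seed=42)


@pytest.fixture(scope="session")
def chain_calib():
    """Calibration of the chain sampling neuron (29.5 ms window)."""
    return calibrate(
        params=SAMPLING_NEURON, duration=50000.0, free_duration=10000.0, seed=43
    )


@pytest.fixture
def chain_bn():
    """Three-node chain Z1 → Z2 → Z3 with hand-chosen conditionals."""
    return BayesianNetwork(
        node_ids=("Z1", "Z2", "Z3"),
        parents={"Z1": (), "Z2": ("Z1",), "Z3": ("Z2",)},
        cpt={"Z1": [0.3], "Z2": [0.2, 0.7], "Z3": [0.4, 0.9]},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
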