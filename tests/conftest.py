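import numpy as np
import pytest

from respkit.respirometry import ChamberSpec, CycleConfig
from respkit.synthetic_data import TrajectorySpec, synthesize_trace


@pytest.fixture
def chamber():
    """Default study chamber holding a 25 g fish."""
    return ChamberSpec(fish_mass_kg=0.025)


@pytest.fixture
def cycle():
    return CycleConfig()


@pytest.fixture
def constant_trace(chamber):
    """2 h noiseless trace at constant MO2 = 180 mg O2 kg-1 h-1."""
    spec = TrajectorySpec("constant", {"value": 180.0}, 120.0)
    return synthesize_trace(spec, chamber, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
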