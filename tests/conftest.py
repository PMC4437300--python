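import numpy as np
import pytest

from asicephys import synth


@pytest.fixture
def cfg():
    """Noiseless default-rate simulation config with a fixed seed."""
    return synth.SimConfig(seed=7)


@pytest.fixture
def cfg_2s():
    """Two-second steps: long enough for late-spiking delays > 1 s."""
    return synth.SimConfig(seed=7, step_duration_s=2.0)


@pytest.fixture
def hill_wt():
    """Planted Hill parameters of the wild-type pH-response curve."""
    from asicephys.kinetics import HillFit

    return HillFit(amax=1.0, ph50=6.3, hill_n=1.8)


@pytest.fixture
def ph_grid():
    return np.array([7.4, 7.0, 6.8, 6.5, 6.3, 6.0, 5.5, 5.0])
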