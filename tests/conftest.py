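import numpy as np
import pytest

from bubblerc import StimulusGeometry


@pytest.fixture
def geometry():
    """Study-scale temporal geometry: 96 frames at 120 Hz, contact at the end."""
    return StimulusGeometry()


@pytest.fixture
def small_geometry():
    """Reduced spatial grid used to keep 2-D tests fast."""
    return StimulusGeometry(n_frames=8, width=60, height=40)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
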