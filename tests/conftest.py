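import numpy as np
import pytest

from centroasym import ImageStack, PairGroundTruth, PolygonROI, render_pair


@pytest.fixture
def uniform_stack():
    """Single-channel flat image, value 10."""
    return ImageStack(np.full((1, 1, 32, 32), 10.0), ["Asl"])


@pytest.fixture
def square_roi():
    """Axis-aligned square whose boundary passes through pixel centers (2..6)."""
    return PolygonROI("cell", "sq", vertices=[(2, 2), (6, 2), (6, 6), (2, 6)])


@pytest.fixture
def noiseless_pair():
    """Deterministic noise-free render of a two-channel centriole pair."""
    truth = PairGroundTruth(
        positions=np.array([[22.0, 32.0], [42.0, 32.0]]),
        true_totals={"Asl": (1000.0, 400.0), "Cnb": (0.0, 900.0)},
        psf_sigma=1.5,
        background=50.0,
        noise_model="none",
    )
    return truth, render_pair(truth)
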