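import numpy as np
import pytest

import dirqa


@pytest.fixture
def rng():
    return np.random.default_rng(20160508)


@pytest.fixture
def textured_volume(rng):
    """A smoothly textured 24³ volume (unit spacing) for alignment tests."""
    base = rng.normal(0.0, 60.0, size=(32, 32, 32))
    # mild smoothing so intensities are correlated like real anatomy
    from scipy.ndimage import gaussian_filter

    return dirqa.ImageVolume(gaussian_filter(base, 1.2)[4:28, 4:28, 4:28], (1.0, 1.0, 1.0))


@pytest.fixture
def bell_params():
    """A low-dose-thorax-like spectral model used across tests."""
    return dirqa.NPSParams(a1=100.0, a2=0.3, a3=0.2, a4=10.0)
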