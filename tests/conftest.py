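import numpy as np
import pytest
from scipy import ndimage

import cardiofunc as cf


@pytest.fixture(scope="session")
def texture_64():
    """Band-pass noise pattern with ~4 px correlation length."""
    rng = np.random.default_rng(0)
    w = rng.normal(size=(64, 64))
    tex = ndimage.gaussian_filter(w, 1.0) - ndimage.gaussian_filter(w, 4.0)
    return 500.0 + 100.0 * (tex - tex.mean()) / tex.std()


@pytest.fixture(scope="session")
def clean_comb_image():
    """Noiseless, jitter-free striation image: period 1.8 um at 0.1 um/px."""
    return cf.generate_striation_image(
        cf.StriationTruth(period_um=1.8), shape=(256, 256), pixel_size_um=0.1
    )


@pytest.fixture(scope="session")
def paced_ratiometric_trace():
    """Noiseless paced (0.5 Hz) ratiometric trace, 20 s at 50 Hz."""
    return cf.generate_calcium_trace(cf.TransientTruth(seed=0))
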