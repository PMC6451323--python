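import numpy as np
import pytest

from zvasc.synthetic_data import PhantomSpec, generate_vessel_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 64³ noise-free phantom shared by feature/segmentation tests."""
    return generate_vessel_phantom(
        PhantomSpec(shape=(64, 64, 64), n_vessels=2, noise_sigma=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def textured_image():
    """A smooth random 2D texture with unambiguous local structure."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(42)
    return gaussian_filter(rng.uniform(0, 100, (300, 300)), 2.0)
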