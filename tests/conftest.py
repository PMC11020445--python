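import numpy as np
import pytest

from ebqspine import CohortConfig, Image2D, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Default-size phantom with zero noise everywhere."""
    cfg = PhantomConfig(noise_sd=0.0, seed=1)
    return cfg, *generate_phantom(cfg)


@pytest.fixture(scope="session")
def small_phantom_cfgs():
    """Two small phantoms (flat and curved endplates) cheap enough for
    the per-pixel brute-force mask oracle."""
    flat = PhantomConfig(image_height_px=80, image_width_px=44,
                         levels=("C4/5", "C5/6"), noise_sd=0.0, seed=2)
    wavy = PhantomConfig(image_height_px=80, image_width_px=44,
                         levels=("C4/5", "C5/6"), noise_sd=0.0,
                         endplate_wave_amp_mm=0.6, seed=3)
    return flat, wavy


@pytest.fixture(scope="session")
def default_cohort_cfg():
    return CohortConfig()


@pytest.fixture()
def flat_image():
    """A 20 x 20 mm canvas at 0.5 mm spacing for hand-built geometry tests."""
    return Image2D(np.ones((40, 40)), 0.5)
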