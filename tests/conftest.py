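import numpy as np
import pytest

import cisternatex as ct


@pytest.fixture
def small_spec():
    """Modest ER-scene spec that fits six default cisternae."""
    return ct.PhantomSpec(image_shape=(192, 192), seed=11)


@pytest.fixture
def noiseless_spec():
    return ct.PhantomSpec(image_shape=(192, 192), seed=11,
                          psf_fwhm_nm=0.0, read_noise_sd=0.0,
                          background_level=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def er_scene(small_spec):
    """Rendered sac ER phantom with ground truth (shared, read-only)."""
    layout = ct.make_er_scene(small_spec, n_cisternae=6, substructure="sac")
    img, gt = ct.render_er_image(layout, small_spec)
    return layout, img, gt
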