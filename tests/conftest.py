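import numpy as np
import pytest

from spinesynth.phantom import LesionSpec, PhantomSpec, build_tissue_map, render_contrast
from spinesynth.volume import ImageVolume, rescale_intensity


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    return PhantomSpec(shape=(12, 48, 48), spacing=(3.0, 1.1, 1.1), n_vertebrae=3,
                       disc_thickness=3, noise_sd=0.0, seed=7)


@pytest.fixture
def t2w_volume(small_spec):
    """A noise-free T2w phantom rescaled to [-1, 1]."""
    t = build_tissue_map(small_spec)
    return rescale_intensity(render_contrast(t, "t2w"))


@pytest.fixture
def random_volume(rng):
    return ImageVolume(rng.random((9, 20, 21)), np.diag([3.0, 1.1, 1.1, 1.0]))
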