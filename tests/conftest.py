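import numpy as np
import pytest

from neuroquant.simulate import (
    GeometryParams,
    PhotophysicsParams,
    make_geometry,
    render,
)

SMALL_GEOMETRY = GeometryParams(image_shape=(256, 256), n_neurons=3, seed=11)


@pytest.fixture(scope="session")
def small_truth():
    """One 256x256 field with 3 neurons: the shared geometric ground truth."""
    return make_geometry(SMALL_GEOMETRY)


@pytest.fixture(scope="session")
def clean_render():
    """Noise-free, blur-free render with enrichment 2 on the shared field
    (fresh truth instance: render records what it drew into the truth)."""
    truth = make_geometry(SMALL_GEOMETRY)
    phys = PhotophysicsParams(mtor_enrichment=2.0)
    image = render(truth, phys)
    return image, truth, phys


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
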