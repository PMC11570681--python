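import numpy as np
import pytest

from msrecon.phantom import (
    default_contrast_model,
    generate_tissue_map,
    make_coil_profile,
    make_dataset,
)


@pytest.fixture(scope="session")
def tissue_map():
    return generate_tissue_map(64, 64, lesion=True, seed=7)


@pytest.fixture(scope="session")
def contrast_model():
    return default_contrast_model()


@pytest.fixture(scope="session")
def noiseless_model():
    return default_contrast_model(noise_sd=0.0)


@pytest.fixture(scope="session")
def coil_profile():
    return make_coil_profile(4, 64, 64, seed=3)


@pytest.fixture(scope="session")
def small_dataset():
    """Two healthy + two patient phantoms, 64x64, 2 coils."""
    return make_dataset(2, 2, 64, seed=5, n_coils=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
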