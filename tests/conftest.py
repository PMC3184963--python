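import numpy as np
import pytest

from fmaquant.geometry import VoxelGeometry
from fmaquant.phantom import PhantomParams, generate_glomerular_phantom, preset_params


@pytest.fixture(scope="session")
def default_geometry():
    return VoxelGeometry()


@pytest.fixture(scope="session")
def small_glom_params():
    """A quick-to-generate glomerular phantom (coarse voxels, sham morphology)."""
    return preset_params("sham", scale="coarse", seed=11)


@pytest.fixture(scope="session")
def small_glom_phantom(small_glom_params):
    return generate_glomerular_phantom(small_glom_params)


@pytest.fixture(scope="session")
def binary_glom_phantom():
    """A phantom rendered with the degenerate imaging model (no degradation)."""
    params = preset_params(
        "sham", scale="coarse", seed=12,
        psf_sigma_xy=0.0, psf_sigma_z=0.0, speckle_amplitude=0.0, noise_sd=0.0,
    )
    return generate_glomerular_phantom(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
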