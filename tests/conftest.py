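import numpy as np
import pytest

from mobydose.decay import lu177
from mobydose.phantom import PhantomSpec, build_phantom

LAMBDA_PHYS = lu177().physical_decay_constant()


@pytest.fixture(scope="session")
def nuclide():
    return lu177()


@pytest.fixture(scope="session")
def small_phantom():
    """Default-anatomy phantom at a coarser grid, shared across tests."""
    spec = PhantomSpec(grid=(80, 80, 220), voxel_size_mm=0.5)
    with pytest.warns(UserWarning):  # marrow annulus quantization at 0.5 mm
        return build_phantom(spec)


@pytest.fixture(scope="session")
def water_block():
    """A single large homogeneous region, much bigger than the beta range."""
    spec = PhantomSpec(
        body_weight_g=380.0,
        organ_masses_g={},
        tumor_mass_g=0.0,
        grid=(80, 80, 220),
        voxel_size_mm=1.0,
    )
    return build_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
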