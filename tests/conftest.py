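import numpy as np
import pytest

from tibmech._fabric import FabricTensor
from tibmech._material import MaterialParams, make_material
from tibmech.synthetic_data import SyntheticSpec, generate_section


@pytest.fixture(scope="session")
def small_spec():
    """Small synthetic section: 64^3 voxels, 9.6 mm cube class."""
    return SyntheticSpec(
        grid_shape=(64, 64, 64),
        spacing=0.15,
        target_bvtv=0.25,
        anisotropy_ratio=1.6,
        cortical_thickness=0.8,
        noise_sd=15.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_section(small_spec):
    return generate_section(small_spec)


@pytest.fixture(scope="session")
def iso_material():
    """Isotropic homogenized material at rho = 1 (solid bone)."""
    return make_material(1.0, FabricTensor.isotropic(fallback=False), MaterialParams())


@pytest.fixture(scope="session")
def params():
    return MaterialParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
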