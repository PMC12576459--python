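import numpy as np
import pytest

from ctdosim.geometry import ScannerGeometry
from ctdosim.phantom import VoxelPhantom, make_synthetic_abdomen
from ctdosim.spectrum import calibrate_filtration, generate_spectrum


@pytest.fixture(scope="session")
def calibrated_spectrum():
    filt = calibrate_filtration(120.0, 10.0, 7.56)
    return generate_spectrum(120.0, 10.0, filt)


@pytest.fixture(scope="session")
def geometry():
    return ScannerGeometry()


@pytest.fixture(scope="session")
def abdomen():
    phantom, organ_geometry = make_synthetic_abdomen(seed=1)
    return phantom, organ_geometry


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def uniform_phantom(material: str, density: float, dims=(20, 20, 10),
                    voxel_mm=(5.0, 5.0, 5.0), label_all: int = 0) -> VoxelPhantom:
    """Homogeneous box phantom centred on the isocenter."""
    sp = np.asarray(voxel_mm, dtype=float)
    dims = tuple(dims)
    origin = -(np.asarray(dims) - 1) / 2 * sp
    mat = np.zeros(dims, dtype=np.int16)
    rho = np.full(dims, density, dtype=np.float32)
    labels = np.full(dims, label_all, dtype=np.int16)
    return VoxelPhantom(mat, rho, labels, sp, origin, [material])
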