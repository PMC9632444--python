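import numpy as np
import pytest

from qsmsci.core import AcquisitionProtocol, ellipsoid_mask
from qsmsci.phantom import (ContrastConfig, build_phantom, simulate_megre,
                            simulate_structural, standard_config)


@pytest.fixture(scope="session")
def standard_truth():
    """The standard 10-lesion phantom on the 64^3 GRE grid."""
    return build_phantom(standard_config())


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def noiseless_series(standard_truth, protocol):
    return simulate_megre(standard_truth, protocol)


@pytest.fixture(scope="session")
def structurals(standard_truth):
    return simulate_structural(standard_truth, ContrastConfig(seed=0))


@pytest.fixture(scope="session")
def sphere_chi():
    """Uniform sphere of 0.1 ppm, radius 8 voxels, centered in a 64^3 grid."""
    shape = (64, 64, 64)
    mask = ellipsoid_mask(shape, (31.5, 31.5, 31.5), (8, 8, 8), (1, 1, 1))
    return np.where(mask, 0.1, 0.0), mask
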