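import numpy as np
import pytest

from ivimdce import DceScheme, DwiScheme, population_aif
from ivimdce.phantom import generate_phantom


@pytest.fixture(scope="session")
def dwi_scheme():
    return DwiScheme()


@pytest.fixture(scope="session")
def dce_scheme():
    return DceScheme()


@pytest.fixture(scope="session")
def aif(dce_scheme):
    return population_aif(dce_scheme)


@pytest.fixture(scope="session")
def b_values(dwi_scheme):
    return np.asarray(dwi_scheme.b_values)


@pytest.fixture()
def small_phantom():
    """Heterogeneous tumor-in-background phantom on a small grid."""
    return generate_phantom(shape=(10, 10, 6), tumor_cv=0.10, seed=11)


@pytest.fixture()
def flat_phantom():
    """Homogeneous all-tumor phantom (every voxel in the ROI, cv=0)."""
    return generate_phantom(shape=(7, 7, 5), tumor_cv=0.0,
                            semi_axes=(99, 99, 99), seed=7)
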