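import numpy as np
import pytest

from glucest import AcquisitionSpec, Pool, make_phantom, simulate_phantom

TEST_MATRIX = (16, 16)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSpec(matrix=TEST_MATRIX)


@pytest.fixture(scope="session")
def water_pool():
    return Pool(shift=0.0, amplitude=0.9, width=1.5, label="water")


@pytest.fixture(scope="session")
def glu_pool():
    return Pool(shift=3.0, amplitude=0.05, width=1.0, label="glu_amine")


@pytest.fixture(scope="session")
def ideal_study(acq):
    """Noiseless subject with b0 = 0 and b1 = 1: the identity configuration."""
    phantom = make_phantom(
        matrix=TEST_MATRIX, b0_max=0.0, b1_range=(1.0, 1.0), noise_sigma=0.0, seed=11
    )
    return simulate_phantom(phantom, acq)


@pytest.fixture(scope="session")
def shifted_study(acq):
    """Noiseless subject with smooth B0 (max 0.3 ppm) and B1 in [0.9, 1.1]."""
    phantom = make_phantom(
        matrix=TEST_MATRIX,
        b0_max=0.3,
        b1_range=(0.9, 1.1),
        noise_sigma=0.0,
        seed=12,
    )
    return simulate_phantom(phantom, acq)


@pytest.fixture(scope="session")
def wassr_offsets():
    return np.linspace(-0.8, 0.8, 33)
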