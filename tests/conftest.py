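import dataclasses

import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from aquamap import AcqProtocol
from aquamap.phantom import PhantomSpec, make_brain_phantom, simulate_echo_series

SMALL_GRID = (32, 32, 16)


@pytest.fixture(scope="session")
def protocol32():
    """32-echo long-TR protocol on the phantom voxel grid."""
    return dataclasses.replace(AcqProtocol.default_3t(32), voxel_mm=(2.0, 2.0, 1.5))


@pytest.fixture(scope="session")
def protocol12(protocol32):
    return dataclasses.replace(AcqProtocol.default_3t(12), voxel_mm=(2.0, 2.0, 1.5))


@pytest.fixture(scope="session")
def brain_truth():
    """Default noise-free brain phantom geometry."""
    return make_brain_phantom(PhantomSpec(kind="brain"))


@pytest.fixture(scope="session")
def noiseless_series(brain_truth, protocol32):
    return simulate_echo_series(brain_truth, protocol32, noise_sd=0.0, seed=0)


def interior(mask: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Erode a mask so forward differences never reach background voxels."""
    return binary_erosion(mask, iterations=iterations)
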