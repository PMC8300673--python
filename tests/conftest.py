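import numpy as np
import pytest

import jacrec as jr
from jacrec.fixtures import asym6


@pytest.fixture(scope="session")
def six_patch_network():
    return asym6()


@pytest.fixture(scope="session")
def metacommunity_pattern(six_patch_network):
    """Cross-layer + spatial zeros of the 2-species, 6-patch system (96 zeros)."""
    idx = jr.MultilayerIndex(2, 6)
    return jr.multilayer_zero_pattern(idx, six_patch_network)


@pytest.fixture(scope="session")
def rm_intra_jacobian():
    """Single-patch Rosenzweig-MacArthur Jacobian at the default coexistence state."""
    model = jr.rm_single_patch_model()
    ss = jr.find_steady_state(model, np.array([0.8, 0.5]))
    return jr.numeric_jacobian(model, ss)


@pytest.fixture(scope="session")
def rm_full_jacobian(rm_intra_jacobian, six_patch_network):
    """12-dim metacommunity Jacobian at the homogeneous default steady state."""
    lap = jr.laplacian_matrix(six_patch_network)
    delta = jr.DEFAULT_RM_PARAMS
    return np.kron(np.eye(6), rm_intra_jacobian) - np.kron(
        lap, np.diag([delta["delta_b"], delta["delta_c"]])
    )
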