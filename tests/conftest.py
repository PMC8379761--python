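import numpy as np
import pytest

from nmblock import base_parameters


@pytest.fixture(scope="session")
def base_params():
    return base_parameters()


@pytest.fixture(scope="session")
def high_affinity_params(base_params):
    """Base case with K_A = 1e-5 M, the setting used for the ACh sweeps."""
    return base_params.with_K_A(1.0e-5)


@pytest.fixture(scope="session")
def coarse_grid():
    """Zero plus 12 log-spaced blocker concentrations spanning the
    occupancy transition (delta ~ 3e-3 .. 1e2 at K_D1 = 1e-7 M)."""
    return np.concatenate(([0.0], np.logspace(-9.5, -5.0, 12)))
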