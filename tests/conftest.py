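import numpy as np
import pytest

from seedrift import Landscape1D, calibrate_kernel


@pytest.fixture
def rng():
    return np.random.default_rng(20230529)


@pytest.fixture
def kernel_fig3a():
    """Kernel of the headline deterministic run (d05=60, d30=700 cells)."""
    return calibrate_kernel(60.0, 700.0)


@pytest.fixture
def flat_kernel():
    """Degenerate calibration with equal medians: lambda = 0.5 at every size."""
    return calibrate_kernel(1.0, 1.0)


@pytest.fixture
def small_window():
    return Landscape1D(x_h=50, x_ipd=10, mode="bounded", d_max=200)
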