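import numpy as np
import pytest

import facespace as fs


@pytest.fixture(scope="session")
def default_grid():
    """Unit-scale polar grid on a D=50 slice (fixed seed)."""
    basis = fs.sample_slice(50, np.random.default_rng(0))
    return fs.build_polar_grid(1.0, basis)


@pytest.fixture(scope="session")
def small_bank():
    """Gabor bank at a reduced 48-px resolution for fast image tests."""
    return fs.build_filter_bank(48, wavelengths=(16.0, 8.0, 4.0, 3.0, 2.0))


@pytest.fixture(scope="session")
def participant():
    """One synthetic participant at the reduced 48-px resolution."""
    return fs.generate_participant(11, resolution=48)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
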