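import numpy as np
import pytest

from cellwatch.synthetic import (SyntheticGrowthParams, SyntheticImageParams,
                                 generate_cell_image, generate_growth_series)


@pytest.fixture(scope="session")
def two_level_params():
    """Artifact-free synthetic frame: pure two-level image, hard edges."""
    return SyntheticImageParams(n_cells=12, halo_amplitude=0.0,
                                shade_off_amplitude=0.0, noise_sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def two_level_image(two_level_params):
    return generate_cell_image(two_level_params)


@pytest.fixture(scope="session")
def default_image():
    """Full-artifact synthetic frame with its truth mask."""
    return generate_cell_image(SyntheticImageParams(seed=11))


@pytest.fixture
def quadratic_series():
    """Noise-free reference quadratic, 700 frames (crosses 0.5 near frame 623)."""
    return generate_growth_series(SyntheticGrowthParams(
        family="quadratic", a2=1e-6, a1=1e-4, c0=0.05, n_frames=700,
        noise_sigma=0.0, seed=0))


@pytest.fixture
def noisy_quadratic_series():
    return generate_growth_series(SyntheticGrowthParams(
        family="quadratic", a2=1e-6, a1=1e-4, c0=0.05, n_frames=600,
        noise_sigma=0.005, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
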