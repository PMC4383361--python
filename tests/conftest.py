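import numpy as np
import pytest

from cfcsim import (
    make_band_spectrum,
    make_noise_spectrum,
    make_theta_spectrum,
    spectrum_to_acv,
)
from cfcsim.sampling import circulant_ensemble, component_factor, draw_ensemble

DELTA = 0.001
N_GRID = 4096  # smaller than the 8192 default: faster, ample for tests


@pytest.fixture(scope="session")
def delta():
    return DELTA


@pytest.fixture(scope="session")
def theta_spec():
    return make_theta_spectrum(6.0, 2.0, 1.0, DELTA, N_GRID)


@pytest.fixture(scope="session")
def noise_spec():
    return make_noise_spectrum(2.0, 1.0, 0.5, DELTA, N_GRID)


@pytest.fixture(scope="session")
def band_spec():
    return make_band_spectrum(100.0, 140.0, 1.0, 4.0, DELTA, N_GRID)


@pytest.fixture(scope="session")
def theta_acv(theta_spec):
    return spectrum_to_acv(theta_spec, 2048)


@pytest.fixture(scope="session")
def band_acv(band_spec):
    return spectrum_to_acv(band_spec, 2048)


@pytest.fixture(scope="session")
def theta_factor_256(theta_spec):
    return component_factor(theta_spec, 256)


@pytest.fixture(scope="session")
def theta_ens_2000(theta_factor_256):
    """2000 Toeplitz-root draws of the slow oscillation at n=256."""
    return draw_ensemble(theta_factor_256, 2000, 20260905)


@pytest.fixture(scope="session")
def theta_circ_2000(theta_acv):
    """2000 circulant-embedding draws at n=256 (independent sampler)."""
    return circulant_ensemble(theta_acv, 256, 2000, 90520262)


def sample_acv_matrix(values: np.ndarray, max_lag: int) -> np.ndarray:
    """Per-column biased sample autocovariances, shape (max_lag+1, n_cols)."""
    n = values.shape[0]
    out = np.empty((max_lag + 1, values.shape[1]))
    for tau in range(max_lag + 1):
        out[tau] = np.mean(values[: n - tau or None] * values[tau:], axis=0)
    return out
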