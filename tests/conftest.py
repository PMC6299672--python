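import numpy as np
import pytest

from nirsfq import SpectralDataset
from nirsfq.workbench import simulate_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(matrix, wavenumbers=None, ids=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = matrix.shape
    if wavenumbers is None:
        wavenumbers = np.linspace(4000.0, 10000.0, p)
    if ids is None:
        ids = [f"S{i:03d}" for i in range(n)]
    return SpectralDataset(ids=ids, wavenumbers=wavenumbers, absorbance=matrix)


@pytest.fixture(scope="session")
def small_campaign_data():
    """One seeded synthetic campaign at full grid scale, shared across tests."""
    library, sim, spectra, reference = simulate_fixture(7, n=60)
    return library, sim, spectra, reference
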