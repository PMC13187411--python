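import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import leafoptics as lo

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_grid():
    return lo.WavelengthGrid.desk()


@pytest.fixture(scope="session")
def constants():
    """Default synthetic optical-constants table on the 51-point desk grid."""
    return lo.synthetic_optical_constants()


@pytest.fixture(scope="session")
def wide_traits():
    """30 leaves drawn from the wide (species-diverse) archetype."""
    return lo.sample_trait_population(lo.wide_population(n_samples=30, seed=7))


@pytest.fixture(scope="session")
def wide_spectra(wide_traits, constants):
    return lo.simulate_spectra(wide_traits, constants)


def make_dataset(values, grid=None, ids=None):
    values = np.asarray(values, dtype=float)
    grid = grid or lo.WavelengthGrid(np.arange(1, values.shape[1] + 1) * 100.0)
    meta = None
    if ids is not None:
        meta = pd.DataFrame({"sample_id": ids})
    return lo.SpectralDataset(grid, values, meta)
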