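import numpy as np
import pytest

from dispersal_ssf import generate_landscape


@pytest.fixture(scope="session")
def landscape():
    """One shared synthetic landscape: minimal 120-km extent, coarsened
    cells (150-m terrain, 500-m NDVI) to keep the suite fast."""
    return generate_landscape((120_000, 120_000), rng_seed=1, terrain_cell=150, ndvi_cell=500)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
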