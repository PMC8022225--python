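import numpy as np
import pytest

import targetsearch as ts


@pytest.fixture(scope="session")
def acq():
    """Default acquisition: 15.48 ms frames, 100 sub-frames, 35 nm error."""
    return ts.AcquisitionModel()


@pytest.fixture(scope="session")
def tube():
    """A single huge cylindrical segment: effectively unconfined diffusion."""
    return ts.CellGeometry([0.0], [200.0], [50.0])


@pytest.fixture(scope="session")
def cell_population():
    """A small population of realistic spherocylinders (r = 0.45 µm)."""
    return ts.default_cell_population(n_cells=20, seed=3)


@pytest.fixture(scope="session")
def rnap_cells():
    """The canonical 50-cell population used for bound-fraction inference."""
    return ts.default_cell_population(n_cells=50, radius=0.45, length_range=(2.0, 4.0), seed=0)


def gamma_dstar(rng, d, n_values, n_steps=4):
    """Ideal D_i* draws for a species with apparent coefficient ``d``."""
    return rng.gamma(n_steps, d / n_steps, size=n_values)
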