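import numpy as np
import pytest

from garddr.benchmark import load_reference_table
from garddr.data import DoseResponseDataset
from garddr.simulate import SimulationSpec, default_grid, simulate_dataset


@pytest.fixture(scope="session")
def grid9():
    """Nine-step assay grid: the 3/5 ladder re-anchored at 500 µM."""
    return default_grid()


@pytest.fixture(scope="session")
def reference_records():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the printed table has one known rounding clash
        return load_reference_table()


@pytest.fixture
def noiseless_dataset():
    """Exact 4PL data from (b=-1.5, c=-1, d=1, e=20) on 9 points over 1-500 µM."""
    spec = SimulationSpec(
        b=-1.5, c=-1.0, d=1.0, e=20.0, noise_sd=0.0,
        grid=np.geomspace(1.0, 500.0, 9), seed=0,
    )
    return simulate_dataset(spec, chemical_id="noiseless")


@pytest.fixture
def flat_dataset(grid9):
    rng = np.random.default_rng(7)
    return DoseResponseDataset.from_arrays(
        "flat", grid9, -1.0 + rng.normal(0.0, 0.05, grid9.size), control_dv=-1.0
    )
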