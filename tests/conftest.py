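import numpy as np
import pytest

from spacetrend import preprocess, synthetic
from spacetrend.grid import TimeGrid
from spacetrend.spectral import spectral_grids


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid()


@pytest.fixture(scope="session")
def sgrids(grid):
    return spectral_grids(grid)


@pytest.fixture(scope="session")
def lag_cohort():
    """Cohort with persisting in-flight rises planted on 6 of 20 measurements
    at high signal-to-noise, classified downstream for recovery checks."""
    base = synthetic.CohortConfig(n_subjects=20, n_measurements=20, n_blocks=1)
    config = synthetic.CohortConfig(
        n_subjects=20, n_measurements=20, n_blocks=1, seed=1,
        assignment={
            (0, m): synthetic.ArchetypeSpec("flight_rise_persist", amplitude=8, noise_sd=1)
            for m in base.measurement_ids()[:6]
        },
    )
    records, truth = synthetic.generate_cohort(config)
    prep = preprocess.preprocess_cohort(records)
    return records, truth, prep


@pytest.fixture(scope="session")
def spike_cohort():
    """Cohort with one landing spike and one landing dip in a 50-measurement
    panel (spikes kept sparse so the subject value pool stays clean)."""
    config = synthetic.CohortConfig(
        n_subjects=20, n_measurements=50, n_blocks=1, seed=2,
        assignment={
            (0, "M001"): synthetic.ArchetypeSpec("landing_spike", amplitude=8, noise_sd=1),
            (0, "M002"): synthetic.ArchetypeSpec("landing_dip", amplitude=8, noise_sd=1),
        },
    )
    records, truth = synthetic.generate_cohort(config)
    prep = preprocess.preprocess_cohort(records)
    return records, truth, prep


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
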