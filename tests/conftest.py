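import numpy as np
import pytest

import lefttrunc as lt

MASTER_SEED = 0
N_REPLICATES = 200
N_TOTAL = 100_000


@pytest.fixture(scope="session")
def primary_grid():
    return lt.build_grid("primary")


@pytest.fixture(scope="session")
def primary_study(primary_grid):
    """Full-scale primary study: 10 setups x 200 replicates x 100,000."""
    return lt.run_study(primary_grid, n_replicates=N_REPLICATES,
                        n_total=N_TOTAL, master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def stillbirth_mirror_grid():
    """The 10 stillbirth setups mirroring the primary grid (setup_id 41-50)."""
    grid = [p for p in lt.build_grid("sensitivity_stillbirth")
            if 41 <= p.setup_id <= 50]
    assert len(grid) == 10
    return grid


@pytest.fixture(scope="session")
def stillbirth_mirror_study(stillbirth_mirror_grid):
    return lt.run_study(stillbirth_mirror_grid, n_replicates=N_REPLICATES,
                        n_total=N_TOTAL, master_seed=MASTER_SEED)


@pytest.fixture()
def cohort(primary_grid):
    """One simulated cohort under the first primary setup."""
    rng = np.random.default_rng(7)
    return lt.simulate_cohort(primary_grid[0], N_TOTAL, rng)


def make_counts(z0_arms, z1_arms, n_pad_cell=(1, 0)):
    """Build a CohortCounts from per-arm (n, n_sab, n_deaths) triples.

    ``z0_arms`` and ``z1_arms`` are dicts {x: (n, sab, deaths)}; deaths occur
    among the C=0 survivors. Used to hand-construct toy cohorts whose risks
    are checkable by pencil-and-paper arithmetic.
    """
    counts = np.zeros((2, 2, 2, 2), dtype=np.int64)
    for z, arms in ((0, z0_arms), (1, z1_arms)):
        for x, (n, sab, deaths) in arms.items():
            counts[z, x, 1, 0] = sab
            counts[z, x, 0, 1] = deaths
            counts[z, x, 0, 0] = n - sab - deaths
    return lt.CohortCounts(n_total=int(counts.sum()), drawn_pX_Z1=0.0275,
                           drawn_pX_Z0=0.0105, counts=counts)
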