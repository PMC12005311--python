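import numpy as np
import pytest

from fibrodefer import CohortConfig, generate_cohort
from fibrodefer.density import ConditionalDensityTable, DensityConfig


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 400-case synthetic cohort shared across tests."""
    return generate_cohort(CohortConfig(n=400, seed=42))


@pytest.fixture()
def hand_table():
    """A hand-fitted 2-bin density table with known masses."""
    t = ConditionalDensityTable(task=2, config=DensityConfig(bins=2))
    t.density = [
        [np.array([0.8, 0.2]), np.array([0.5, 0.5])],
        [np.array([0.5, 0.5]), np.array([0.5, 0.5])],
    ]
    t.prior = np.array([[0.9, 0.3], [0.1, 0.7]])
    t.counts = np.ones((2, 2), dtype=int)
    return t


def random_density_table(rng, task=2):
    """A randomly fitted small density table (T <= 20) for oracle checks."""
    T = int(rng.integers(2, 21))
    cfg = DensityConfig(
        bins=T,
        bandwidth=float(rng.choice([0.0, 0.5, 1.0])),
        pseudocount=float(rng.choice([0.0, 0.5, 1.0])),
        prior_smoothing=0.5,
    )
    n = int(rng.integers(30, 120))
    y = rng.integers(0, 2, n)
    h = np.where(rng.random(n) < 0.75, y, 1 - y)
    # bimodal scores loosely tracking the truth
    z = np.clip(rng.beta(2, 5, n) + 0.5 * y + rng.normal(0, 0.1, n), 0, 1)
    from fibrodefer.density import fit_density_table

    return fit_density_table(z, h, y, task, cfg)
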