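import numpy as np
import pytest

from phconnectome import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def small_cohort():
    """16-ROI, 8+8 cohort with a moderate planted effect (session-cached)."""
    spec = CohortSpec(
        n_carriers=8, n_noncarriers=8, n_rois=16, n_timepoints=120,
        n_modules=4, effect_size=0.5, seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture
def random_distance(rng):
    """Factory for random symmetric distance networks with entries in (0, 1)."""

    def make(m: int, full_range: bool = True) -> np.ndarray:
        d = np.zeros((m, m))
        iu = np.triu_indices(m, k=1)
        d[iu] = rng.uniform(0.05, 0.95, size=len(iu[0]))
        d += d.T
        return d

    return make
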