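import numpy as np
import pytest

from kronsurv.survival import SurvivalData
from kronsurv.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort reused by unit tests (not the acceptance conditions)."""
    cfg = CohortConfig(n_patients=80, n_genes=60, n_cpgs=120, n_pathways=10,
                       genes_per_pathway=6, grid_size=6, patch_embed_dim=8,
                       seed=2024)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_survival(rng, n, hazard=None, censor_scale=2.0):
    """Exponential survival helper for statistics tests."""
    eta = np.zeros(n) if hazard is None else np.asarray(hazard)
    T = rng.exponential(np.exp(-eta))
    C = rng.exponential(censor_scale, size=n)
    t = np.maximum(np.minimum(T, C), 1e-9)
    return SurvivalData(t, (T <= C).astype(int))
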