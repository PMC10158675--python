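import numpy as np
import pytest

from modsew.features import FEATURE_NAMES, build_entries
from modsew.scoring import ScoreTable
from modsew.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def table():
    return ScoreTable.default()


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_patients=20, mods_prevalence=0.5, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_entries(small_cohort):
    cohort, truth = small_cohort
    return build_entries(cohort, truth)


@pytest.fixture(scope="session")
def separable_data():
    """Linearly separable 2-feature binary set (n=500, seed 1)."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(500, 2))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    return X, y


@pytest.fixture(scope="session")
def feature_names():
    return list(FEATURE_NAMES)
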