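import numpy as np
import pytest

from kelmplus.ensemble import EnsembleConfig
from kelmplus.pipeline import prepare_features
from kelmplus.synthetic import SyntheticSpec, generate_cohort, labels_from_meta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small two-grade cohort with a strong effect, shared across tests."""
    spec = SyntheticSpec(n_per_grade=12, grades=(1, 4), effect_size=2.0, seed=7)
    tables, stats, metas = generate_cohort(spec)
    return tables, stats, metas


@pytest.fixture(scope="session")
def tiny_matrices(tiny_cohort):
    tables, stats, metas = tiny_cohort
    matrices, names = prepare_features(tables, stats)
    return matrices, names, labels_from_meta(metas)


@pytest.fixture
def fast_config():
    """Singleton grids: no tuning, closed-form training only."""
    return EnsembleConfig(main="GMV", C_grid=(1.0,), eps_grid=(1.0,),
                          gamma_scale_grid=(1.0,), k=10, seed=0)
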