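import numpy as np
import pytest

from longicog.features import BaselineChangeFeaturizer
from longicog.pipeline import prepare_pairs
from longicog.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimulationConfig(n_patients=80, effect_size=1.5, seed=5))


@pytest.fixture(scope="session")
def prepared(small_cohort):
    return prepare_pairs(small_cohort, k=3, seed=2)


@pytest.fixture(scope="session")
def engineered(prepared):
    """(train samples, eval samples, featurizer) for fold 0 of the small cohort."""
    featurizer = BaselineChangeFeaturizer(prepared.cohort.feature_specs)
    train_pairs = prepared.train_pairs_for_fold(0)
    eval_pairs = prepared.eval_pairs_for_fold(0)
    train = featurizer.fit(train_pairs).transform(train_pairs)
    evals = featurizer.transform(eval_pairs)
    return train, evals, featurizer


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
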