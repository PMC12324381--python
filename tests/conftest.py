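import numpy as np
import pytest

from bristlekit.features import PatternFeaturizer
from bristlekit.stats import Cohort
from bristlekit.synthetic import simulate_cohort

TWO_SQUARES = np.array(
    [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0],
     [100.0, 0.0], [101.0, 0.0], [100.0, 1.0], [101.0, 1.0]]
)

LINE_TWO_CLUSTERS = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 0.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Featurised wildtype vs dense_heterogeneous cohort (12 vs 12).

    Session-scoped because featurisation dominates test runtime; tests
    must not mutate it.
    """
    patterns, pairing = simulate_cohort(
        {"wildtype": ("wildtype", 12), "dense_heterogeneous": ("dense_heterogeneous", 12)},
        master_seed=42,
    )
    table = PatternFeaturizer().fit_transform(patterns)
    return Cohort(features=table, pairing=pairing)
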