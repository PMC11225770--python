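import numpy as np
import pytest

from paddypest.loa import LOAConfig
from paddypest.selection import FeatureMatrix
from paddypest.synthetic import SyntheticSpec, generate_feature_table


@pytest.fixture(scope="session")
def recovery_table():
    """The two-class Gaussian table used by the wrapper-recovery checks:
    200 samples/class, 50 features, 10 informative, separation 2 SD."""
    spec = SyntheticSpec(n_per_class=200, d=50, n_informative=10,
                         separation=2.0, seed=7)
    X, y, informative = generate_feature_table(spec)
    return FeatureMatrix(values=X), y, informative


@pytest.fixture
def small_config():
    """Factory for a small, fast optimizer configuration."""

    def make(dim=3, **overrides):
        defaults = dict(
            lower_bounds=np.full(dim, -5.0),
            upper_bounds=np.full(dim, 5.0),
            population_size=30,
            num_prides=3,
            max_iterations=10,
            patience=0,
            seed=0,
        )
        defaults.update(overrides)
        return LOAConfig(**defaults)

    return make


def sphere(x):
    return float(np.sum(x * x))


@pytest.fixture
def sphere_objective():
    return sphere
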