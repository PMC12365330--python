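import numpy as np
import pytest

from cfsa import Bounds, Dataset, FitnessSpec, SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def bounds3():
    return Bounds(0.0, 1.0, 3)


@pytest.fixture(scope="session")
def fast_spec():
    """Cheap deterministic wrapper objective for optimizer tests."""
    return FitnessSpec(classifier="knn", cv_folds=3, cv_seed=11)


@pytest.fixture(scope="session")
def separable_dataset():
    """n=60, d=3: feature 0 separates the classes with a wide margin,
    features 1-2 are pure noise."""
    rng = np.random.default_rng(42)
    n = 60
    y = np.array([0, 1] * (n // 2))
    X = rng.standard_normal((n, 3))
    X[:, 0] = np.where(y == 1, 2.0, -2.0) + 0.1 * rng.standard_normal(n)
    return Dataset(
        features=X,
        feature_names=["f0", "f1", "f2"],
        feature_kinds=["numeric"] * 3,
        target=y,
        missing_mask=np.zeros((n, 3), dtype=bool),
        provenance="synthetic",
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """The d=8 study problem: 2 strongly informative features among 8."""
    return generate_synthetic(
        SyntheticSpec(
            n=300,
            d=8,
            informative=(0, 1),
            effect_size=3.0,
            class_balance=0.3,
            seed=7,
        )
    )
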