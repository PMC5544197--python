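import numpy as np
import pytest

from ranksig.io import CohortLabels, ExpressionMatrix
from ranksig.simulate import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    values = np.array(
        [
            [1.0, 2.0, 3.0],
            [4.0, 5.0, 6.0],
            [7.0, 8.0, 9.0],
            [0.5, 0.1, 0.9],
        ]
    )
    return ExpressionMatrix(["p1", "p2", "p3", "p4"], ["s1", "s2", "s3"], values)


@pytest.fixture
def random_matrix(rng):
    n_probes, n_samples = 30, 8
    return ExpressionMatrix(
        [f"p{i:03d}" for i in range(n_probes)],
        [f"s{j}" for j in range(n_samples)],
        rng.normal(size=(n_probes, n_samples)),
    )


def strong_cohort(seed: int = 0, **overrides):
    """Cohort with a strong planted signal; downstream stages classify it perfectly."""
    kwargs = dict(
        n_probes=500,
        n_per_group=10,
        n_diff_probes=10,
        log2fc=2.0,
        noise_sd=0.2,
        n_sets=5,
        set_size_range=(12, 16),
        enriched_fraction=1.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return generate_cohort(SyntheticConfig(**kwargs))


@pytest.fixture
def strong(seed=0):
    return strong_cohort(0)


@pytest.fixture
def two_class_labels():
    def make(sample_ids, classes=("A", "B")):
        half = len(sample_ids) // 2
        labels = {s: (classes[0] if i < half else classes[1]) for i, s in enumerate(sample_ids)}
        return CohortLabels(labels, list(classes))

    return make
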