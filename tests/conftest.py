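import numpy as np
import pytest

from pcufe import (
    CohortParams,
    ExpressionMatrix,
    SampleAnnotation,
    generate_two_class_cohort,
    log_transform,
    normalize_samples,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_normalized_matrix(rng, n=10, m=4):
    """Random matrix already satisfying the per-sample constraints."""
    raw = ExpressionMatrix(
        feature_ids=[f"f{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(m)],
        values=rng.normal(size=(n, m)),
    )
    return normalize_samples(raw)


@pytest.fixture
def small_normalized(rng):
    return random_normalized_matrix(rng, n=10, m=4)


@pytest.fixture
def balanced_annot():
    return SampleAnnotation(
        sample_ids=["s0", "s1", "s2", "s3"],
        class_labels=["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def strong_cohort():
    """Well-separated cohort (small, fast) with ground truth."""
    params = CohortParams(
        n_features=400,
        n_samples_class1=15,
        n_samples_class2=15,
        n_informative=10,
        effect_size=3.0,
        noise_sd=1.0,
        seed=7,
    )
    return generate_two_class_cohort(params)


@pytest.fixture(scope="session")
def strong_normalized(strong_cohort):
    return normalize_samples(log_transform(strong_cohort.matrix))
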