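import numpy as np
import pytest

from admorph.data_io import FeatureTable
from admorph.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    """4-subject, 2-feature, 2-class table."""
    return FeatureTable(
        subject_ids=("s1", "s2", "s3", "s4"),
        labels=("NC", "NC", "AD", "AD"),
        feature_names=("f1", "f2"),
        values=np.array([[1.0, 2.0], [1.5, 2.5], [3.0, 4.0], [3.5, 4.5]]),
    )


@pytest.fixture
def small_cohort():
    """Small separable 3-class cohort (fast fixture for harness tests)."""
    return generate_cohort(CohortSpec(n_per_class=(15, 15, 15), n_features=8,
                                      n_affected=4, effect=2.0, seed=11))


@pytest.fixture
def default_cohort():
    """The default study-sized cohort: 70/74/70 subjects, 54 features."""
    return generate_cohort(CohortSpec(seed=5))
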