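import numpy as np
import pytest

from ssmnet import GroundTruth, generate_cohort, generate_study


@pytest.fixture(scope="session")
def small_truth():
    return GroundTruth.default(n_tracts=12, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    """Single-metric cohort, 40 participants x 12 tracts."""
    return generate_cohort(40, 12, small_truth)


@pytest.fixture(scope="session")
def four_metric_study():
    """Four-metric cohort for QC and pipeline tests (36 x 10)."""
    truth = GroundTruth.default(n_tracts=10, seed=3)
    return generate_study(36, 10, truth)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
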