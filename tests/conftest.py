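import numpy as np
import pytest

from cytodose.dataprep import compute_indices, encode_features, filter_low_counts
from cytodose.synthdata import GeneratorConfig, generate_default_cohort


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (~1395 rows pre-filter)."""
    return generate_default_cohort(0)


@pytest.fixture(scope="session")
def records(cohort):
    """Filtered cohort with indices computed at the generating k."""
    retained, _ = filter_low_counts(cohort)
    return compute_indices(retained, 70)


@pytest.fixture(scope="session")
def matrix(records):
    return encode_features(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
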