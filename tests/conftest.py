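import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fmtrack import (
    SyntheticConfig,
    classify_inoculum_asvs,
    filter_low_count_features,
    generate_dataset,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study shared across the suite."""
    return generate_dataset(seed=101)


@pytest.fixture(scope="session")
def filtered(dataset):
    return filter_low_count_features(dataset.table)


@pytest.fixture(scope="session")
def classification(dataset, filtered):
    inocula = filtered.subset_samples(dataset.config.donors)
    baseline = filtered.subset_samples(
        [s for s in filtered.sample_ids if s.endswith("_PND21")]
    )
    return classify_inoculum_asvs(inocula, baseline)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study for tests that regenerate data repeatedly."""
    return SyntheticConfig(
        donor_richness=(60, 40),
        n_common_with_baseline=(15, 12),
        n_shared_unique=6,
        n_piglets_per_group=4,
        n_baseline_only=60,
        baseline_richness=40,
        depth=20_000,
        inoculum_depth=60_000,
        n_metabolites=20,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)
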