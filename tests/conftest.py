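import numpy as np
import pytest

from popproxy import DistanceMatrix, SyntheticStudyConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_distance_matrix(rng, n, level="population", labels=None):
    """A random valid distance matrix (not necessarily metric)."""
    a = rng.uniform(0.1, 5.0, size=(n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = labels or [f"U{i}" for i in range(n)]
    return DistanceMatrix(labels, d, level=level)


@pytest.fixture
def small_study_config():
    """A compact study: quick to generate, full structure."""
    return SyntheticStudyConfig(
        n_populations=5,
        n_tanks_per_population=3,
        trait_names=["survival_rate", "activity"],
        coupling={"survival_rate": ("genetic", 0.8)},
        noise_sd=0.2,
        haplotype_length=300,
        n_sequences_per_population=6,
        raster_shape=(15, 15),
        seed=7,
    )


@pytest.fixture
def small_study(small_study_config):
    return generate_study(small_study_config)
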