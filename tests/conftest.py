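import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_blob_points(rng):
    """Two well-separated 20-point blobs plus 3 remote singletons."""
    a = rng.normal(loc=(0.0, 0.0), scale=0.05, size=(20, 2))
    b = rng.normal(loc=(10.0, 10.0), scale=0.05, size=(20, 2))
    singles = np.array([[50.0, -50.0], [-40.0, 60.0], [100.0, 100.0]])
    return np.vstack([a, b, singles])


@pytest.fixture
def three_species_community():
    """Small community: 3 species with distinct GC and coverage."""
    from duobin.simulate import CommunitySpec, generate_community

    spec = CommunitySpec(
        n_genomes=3,
        n_coverage_distributions=3,
        coverage_centers=(5.0, 50.0, 300.0),
        genome_length=60_000,
        contig_length_range=(1000, 4000),
        gc_range=(0.30, 0.65),
        seed=7,
    )
    return generate_community(spec)
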