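import numpy as np
import pytest

from ribovar import CommunitySpec, ReadSimSpec, simulate_community, simulate_hifi_reads


@pytest.fixture(scope="session")
def small_truth():
    """One species, one strain, 6-11 copies: the single-sample study unit."""
    return simulate_community(
        CommunitySpec(n_species=1, strains_per_species=1, seed=11)
    )


@pytest.fixture(scope="session")
def small_reads(small_truth):
    reads, origins = simulate_hifi_reads(small_truth, ReadSimSpec(depth=20, seed=12))
    return reads, origins


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
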