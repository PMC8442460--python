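import pytest

from phasekit import simulate as sim
from phasekit import variant_io as vio


@pytest.fixture(scope="session")
def truth():
    """Ten phased blocks of 20 het sites on the toy contig."""
    return sim.simulate_truth(n_blocks=10, sites_per_block=20, seed=11)


@pytest.fixture(scope="session")
def reads(truth):
    """Error-free haplotagged reads over the truth callset."""
    return sim.simulate_haplotagged_reads(truth, n_reads=3000, seed=11)


@pytest.fixture(scope="session")
def tags(reads):
    return reads[0]


@pytest.fixture(scope="session")
def tag_map(tags):
    return vio.tag_mapping(tags)
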