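import pytest
from hypothesis import HealthCheck, settings

from cobind import simulate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def universe_small():
    """300 genes on three 5-Mb chromosomes; shared across read-only tests."""
    sizes = {"chr1": 5_000_000, "chr2": 5_000_000, "chr3": 5_000_000}
    return simulate.simulate_gene_universe(n_genes=300, chrom_sizes=sizes, seed=11)


@pytest.fixture(scope="session")
def universe_mid():
    """2,000 genes at the default desk-scale genome."""
    return simulate.simulate_gene_universe(n_genes=2_000, seed=5)
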