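import numpy as np
import pytest

from secoer import generate_panel, generate_recmap


@pytest.fixture(scope="session")
def small_panel():
    """20 founder haplotypes, 300 SNPs on a 2 Mb arm: cheap enough for
    per-test simulation."""
    return generate_panel(n_hap=20, n_snps=300, chrom_length=2_000_000,
                          n_prototypes=6, block_length=50_000, seed=11)


@pytest.fixture(scope="session")
def small_recmap(small_panel):
    # ~2.1 cM/Mb, the genome-wide average used for the full-size arm
    return generate_recmap(small_panel.chrom_length, 10, 0.042, seed=12)


@pytest.fixture(scope="session")
def desk_panel():
    """The desk-scale study panel: 100 founder lines, 5,000 SNPs, 23.5 Mb."""
    return generate_panel(seed=101)


@pytest.fixture(scope="session")
def desk_recmap(desk_panel):
    """0.5 Morgan female map over the 23.5 Mb arm, 100 windows."""
    return generate_recmap(desk_panel.chrom_length, 100, 0.5, seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
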