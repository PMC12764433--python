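import numpy as np
import pytest

from neoedit.genemodel import GeneModel
from neoedit.simulate import SimConfig, simulate_cohort, simulate_genome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def toy_gene():
    # M A Q L F K L * on the plus strand, single exon at chr1:100
    return GeneModel(
        gene_id="G1",
        gene_name="toy",
        chrom="chr1",
        strand="+",
        cds_intervals=((100, 124),),
        cds_seq="ATGGCCCAGCTGTTCAAGCTGTAA",
    )


@pytest.fixture()
def toy_gene_minus():
    # same protein on the minus strand; genomic forward = revcomp(cds)
    return GeneModel(
        gene_id="G2",
        gene_name="toy_minus",
        chrom="chr1",
        strand="-",
        cds_intervals=((200, 224),),
        cds_seq="ATGGCCCAGCTGTTCAAGCTGTAA",
    )


@pytest.fixture(scope="session")
def small_genome(rng):
    """A compact random gene space shared by oracle-style tests."""
    config = SimConfig(seed=77, n_genes=40, mean_cds_len=900, n_fabp=6, n_mbp=8)
    return simulate_genome(config)


@pytest.fixture(scope="session")
def mini_cohort():
    """A small but complete cohort for pipeline-level tests."""
    config = SimConfig(
        seed=5,
        n_genes=80,
        mean_cds_len=900,
        n_fabp=12,
        n_mbp=14,
        n_wt=4,
        n_dngr1ko=4,
        n_rag1ko=3,
        burden_low=60,
        burden_high=90,
    )
    return simulate_cohort(config)
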