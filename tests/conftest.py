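import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from geomgenome.intervals import ChromosomeLayout, GenomicInterval
from geomgenome.simulate import GenomeSpec, generate_genome


@pytest.fixture
def toy_layout():
    """Exons [100,200) and [500,600) on a 1000-bp chromosome, positive."""
    return ChromosomeLayout(
        chrom="chr1", orientation="+", length=1000,
        exon_starts=np.array([100, 500]), exon_ends=np.array([200, 600]),
    )


@pytest.fixture
def toy_layout_neg(toy_layout):
    return ChromosomeLayout(
        chrom="chr1", orientation="-", length=1000,
        exon_starts=toy_layout.exon_starts.copy(),
        exon_ends=toy_layout.exon_ends.copy(),
    )


@pytest.fixture(scope="session")
def default_genome():
    """One default-world synthetic genome shared by read-only tests."""
    return generate_genome(GenomeSpec(n_genes=500, seed=42))


@pytest.fixture(scope="session")
def dense_genome():
    """Dense ~9.8%-exonic genome (window-analysis validity regime)."""
    spec = GenomeSpec(n_genes=1000, exonic_fraction=0.098,
                      exon_total_range=(1000, 6000),
                      exon_count_range="auto", hinge_rate=None, seed=7)
    return generate_genome(spec)


def random_layout(rng, n_exons=30, length=100_000):
    """Random valid layout: disjoint sorted exons on [0, length)."""
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons,
                              replace=False))
    starts, ends = cuts[0::2], cuts[1::2]
    return ChromosomeLayout(chrom="chrR", orientation="+", length=length,
                            exon_starts=starts, exon_ends=ends)
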