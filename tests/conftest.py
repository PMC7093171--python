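import numpy as np
import pytest

from ssrmine.simulate import GenomeSimSpec, simulate_genome


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic genome bundle (500 planted SSRs, three 120 kb
    sequences); session-scoped because several suites reuse it."""
    return simulate_genome(seed=0)


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast genome for pipeline/CLI round trips."""
    spec = GenomeSimSpec(
        seq_lengths=(40_000, 40_000),
        genes_per_seq=3,
        te_per_seq=8,
        n_ssrs=120,
    )
    return simulate_genome(spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


#: toy single-gene annotation: + strand gene 101-400, exons 101-180 and
#: 301-400, CDS split 141-180 / 301-340, on a 1000 bp sequence
TOY_GFF = """##gff-version 3
chr1\ttest\tgene\t101\t400\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1
chr1\ttest\texon\t101\t180\t.\t+\t.\tID=t1.e1;Parent=t1
chr1\ttest\texon\t301\t400\t.\t+\t.\tID=t1.e2;Parent=t1
chr1\ttest\tCDS\t141\t180\t.\t+\t0\tID=t1.c1;Parent=t1
chr1\ttest\tCDS\t301\t340\t.\t+\t0\tID=t1.c2;Parent=t1
"""


@pytest.fixture()
def toy_gff():
    return TOY_GFF
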