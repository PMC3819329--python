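import numpy as np
import pytest

from corridorgen import simdata
from corridorgen.genio import GenotypeTable


@pytest.fixture
def two_pop_table():
    """Two well-differentiated populations, 14 loci, 15 diploids each."""
    cfg = simdata.SimGenotypeConfig(n_pops=2, n_per_pop=(15, 15), n_loci=14,
                                    n_alleles=10, F=0.15, seed=11)
    freqs = simdata.sim_allele_freqs(cfg)
    table, _ = simdata.sim_genotypes(freqs, cfg)
    return table, freqs, cfg


@pytest.fixture
def tiny_table():
    """Hand-built 2-population, 2-locus table."""
    calls = np.array([
        [[1, 1], [2, 3]],
        [[1, 2], [3, 3]],
        [[2, 2], [2, 3]],
        [[1, 1], [2, 2]],
    ])
    return GenotypeTable(ids=["a1", "a2", "b1", "b2"],
                         pops=["A", "A", "B", "B"],
                         loci=["L1", "L2"], calls=calls)
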