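import numpy as np
import pytest

from lakelock.genotype_io import MISSING, GenotypeMatrix, PopulationMap
from lakelock.synthetic import make_toy_fixtures


@pytest.fixture(scope="session")
def toy_fixtures():
    return make_toy_fixtures()


def random_matrix(rng, n_samples, n_loci, missing_rate=0.15):
    """A random small genotype matrix with some missing cells."""
    calls = rng.integers(0, 3, size=(n_samples, n_loci)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = MISSING
    sample_ids = [f"s{i}" for i in range(n_samples)]
    locus_ids = [f"c1:{j + 1}" for j in range(n_loci)]
    return GenotypeMatrix(sample_ids, locus_ids, calls)


def random_instance(seed, max_pops=3, max_per_pop=6, max_loci=5):
    """Random small matrix + popmap, guaranteeing every group >= 2 samples
    and every locus called at least once per group."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, max_pops + 1))
    sizes = rng.integers(2, max_per_pop + 1, size=k)
    n = int(sizes.sum())
    n_loci = int(rng.integers(2, max_loci + 1))
    g = random_matrix(rng, n, n_loci)
    codes = np.repeat(np.arange(k), sizes)
    # ensure at least one called genotype per group per locus
    start = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    for gi in range(k):
        for l in range(n_loci):
            block = g.calls[start[gi]:start[gi] + sizes[gi], l]
            if (block == MISSING).all():
                block[0] = int(rng.integers(0, 3))
    pops = PopulationMap({f"s{i}": f"P{codes[i]}" for i in range(n)})
    return g, pops, codes, k
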