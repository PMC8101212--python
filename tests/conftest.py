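import numpy as np
import pytest

from msatpop.synth import default_loci, make_island_world
from msatpop.types import GenotypeMatrix, LocusDef


def build_gm(genotypes, loci=None, populations=None, metadata=None):
    """Compact literal constructor for tests.

    ``genotypes``: list of rows, each a list of (a, b) tuples or None for
    missing; allele values are plain ints placed on a permissive locus.
    """
    n = len(genotypes)
    L = len(genotypes[0])
    if loci is None:
        loci = [
            LocusDef(name=f"L{j + 1}", motif_length=2, size_range=(1, 10_000), missing_code=0)
            for j in range(L)
        ]
    calls = np.full((n, L, 2), -1, dtype=np.int64)
    for i, row in enumerate(genotypes):
        for j, cell in enumerate(row):
            if cell is not None:
                calls[i, j, :] = cell
    if populations is None:
        populations = ["pop1"] * n
    individuals = [f"i{k}" for k in range(n)]
    return GenotypeMatrix(individuals, loci, calls, populations, metadata)


@pytest.fixture(scope="session")
def island_world():
    gm, truth = make_island_world(4, 20, target_fst=0.2, seed=101)
    return gm, truth


@pytest.fixture(scope="session")
def small_world():
    gm, truth = make_island_world(3, 12, target_fst=0.15, seed=202)
    return gm, truth


@pytest.fixture(scope="session")
def loci15():
    return default_loci()
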