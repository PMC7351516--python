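import numpy as np
import pytest

from primpop.snp_data import GenotypeMatrix, PopulationMap, MISSING


@pytest.fixture
def toy_matrix():
    """2 populations x 4 individuals x 3 loci with one missing call."""
    geno = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, MISSING],
            [2, 2, 1],
            [0, 0, 1],
            [1, 0, 2],
            [2, 1, 1],
            [1, 2, 0],
        ],
        dtype=np.int16,
    )
    ids = [f"ind{i}" for i in range(8)]
    g = GenotypeMatrix(geno, ids, ["L1", "L2", "L3"])
    pm = PopulationMap({ids[i]: ("A" if i < 4 else "B") for i in range(8)})
    return g, pm


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(geno, pops, grouping=None):
    """Helper: matrix + map from a genotype array and per-row population labels."""
    geno = np.asarray(geno, dtype=np.int16)
    ids = [f"i{k}" for k in range(geno.shape[0])]
    g = GenotypeMatrix(geno, ids, [f"L{j}" for j in range(geno.shape[1])])
    pm = PopulationMap(dict(zip(ids, pops)), grouping)
    return g, pm
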