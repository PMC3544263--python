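import numpy as np
import pandas as pd
import pytest

from hitchmap.genodata import GenotypeMatrix, MarkerMap


def make_sample(name: str, calls: np.ndarray, loci=None) -> GenotypeMatrix:
    n, L, _ = calls.shape
    return GenotypeMatrix(
        name=name,
        individuals=[f"{name}_{i + 1}" for i in range(n)],
        loci=loci or [f"L{j + 1}" for j in range(L)],
        calls=calls,
    )


def random_dataset(rng, n_pops=2, n_ind=8, n_loci=5, max_allele=4, missing_rate=0.1):
    loci = [f"L{j + 1}" for j in range(n_loci)]
    pops = []
    for p in range(n_pops):
        calls = rng.integers(1, max_allele + 1, size=(n_ind, n_loci, 2)).astype(np.int32)
        miss = rng.random((n_ind, n_loci)) < missing_rate
        calls[miss] = 0
        pops.append(make_sample(f"pop{p + 1}", calls, loci=loci))
    return pops


@pytest.fixture
def tiny_map():
    return MarkerMap(
        pd.DataFrame(
            {
                "locus": ["L1", "L2", "L3", "L4", "L5", "L6"],
                "linkage_group": ["g1", "g1", "g1", "g2", "g2", "g3"],
                "position_female_cM": [0.0, 0.5, 7.9, 46.3, 46.3, 12.0],
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
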