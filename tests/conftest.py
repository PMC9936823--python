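import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from beefq.io import GenotypeMatrix, PhenotypeTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_geno(codes, chrom=None, pos=None):
    """GenotypeMatrix from a plain codes array with generated metadata."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    meta = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "snp_id": [f"s{j}" for j in range(m)],
            "cm": 0.0,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeMatrix(codes=codes, snp_meta=meta,
                          animal_ids=[f"a{i}" for i in range(n)])


@pytest.fixture
def tiny_geno():
    return make_geno([[0, 1], [2, 1], [1, -1]])


@pytest.fixture
def random_geno():
    rng = np.random.default_rng(42)
    p = rng.uniform(0.1, 0.9, 50)
    codes = rng.binomial(2, p, size=(30, 50)).astype(np.int8)
    return make_geno(codes)


def make_phenotypes(n, seed=0, n_cg=3):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(n)],
            "tender": rng.uniform(30, 80, n),
            "juicy": rng.uniform(30, 80, n),
            "flavor": rng.uniform(30, 80, n),
            "overall": rng.uniform(30, 80, n),
            "mq4": rng.uniform(30, 80, n),
            "cg": [f"cg{i % n_cg}" for i in range(n)],
            "days_aged": rng.integers(3, 36, n),
            "carcass_weight": rng.normal(261, 74, n),
        }
    )
    return PhenotypeTable(data=df)
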