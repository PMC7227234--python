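import numpy as np
import pandas as pd
import pytest

from ovipop.genotypes import SNP_COLUMNS, GenotypeMatrix, SampleTable


def make_gm(calls, positions=None, chroms=None, samples=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a dosage array with minimal boilerplate."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_snps = calls.shape
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 1000
    if chroms is None:
        chroms = ["1"] * n_snps
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(n_snps)],
            "chrom": chroms,
            "pos": positions,
            "allele_a": "A",
            "allele_b": "B",
        }
    )[SNP_COLUMNS]
    return GenotypeMatrix(samples, snps, calls)


def make_table(gm: GenotypeMatrix, breeds, metapop=None) -> SampleTable:
    rows = []
    for i, s in enumerate(gm.samples):
        rows.append(
            {
                "id": s,
                "breed": breeds[i],
                "region": None,
                "lat": None,
                "lon": None,
                "metapop": metapop[i] if metapop else None,
            }
        )
    return SampleTable(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_gm(rng):
    calls = rng.integers(0, 3, size=(12, 200)).astype(np.int8)
    return make_gm(calls)
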