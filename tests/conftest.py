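import numpy as np
import pytest

from domestiscan.popio import GenotypeMatrix, PopulationMap


def random_genotype_matrix(rng, n_variants=20, n_samples=8, missing=0.0, contig="chr1"):
    """Small random biallelic matrix; every variant polymorphic."""
    while True:
        counts = rng.integers(0, 3, size=(n_variants, n_samples)).astype(np.int8)
        if missing:
            counts[rng.random(counts.shape) < missing] = -1
        poly = [
            0 < counts[v][counts[v] >= 0].sum() < 2 * (counts[v] >= 0).sum()
            for v in range(n_variants)
        ]
        if all(poly):
            break
    positions = np.sort(rng.choice(np.arange(1, 100_000), size=n_variants, replace=False))
    return GenotypeMatrix(
        contigs=np.array([contig] * n_variants, dtype=object),
        positions=positions.astype(np.int64),
        ref=np.array(["A"] * n_variants, dtype=object),
        alt=np.array(["T"] * n_variants, dtype=object),
        counts=counts,
        vtype=np.array(["snp"] * n_variants, dtype=object),
        samples=[f"s{i:02d}" for i in range(n_samples)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix(rng):
    return random_genotype_matrix(rng)


@pytest.fixture
def two_group_map(small_matrix):
    half = small_matrix.n_samples // 2
    return PopulationMap(
        {s: ("A" if i < half else "B") for i, s in enumerate(small_matrix.samples)},
        ["A", "B"],
    )
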