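"""Shared fixtures and the independent brute-force kinship oracle.

The oracle re-derives the relationship estimator with plain Python loops
straight from its definition — observed allele frequency over non-missing
genotypes, mean-imputed centering, per-pair sum of products over SNPs — and
never touches the package's vectorized code paths.
"""

import numpy as np
import pytest

MISSING = -1


def naive_grm(x, weights=None):
    """Double-loop VanRaden kinship on a raw dosage matrix (lists or array).

    Returns (G, denominator) as plain nested lists / float.  Missing entries
    are coded as -1 and handled exactly as the package specifies: observed
    frequency over the non-missing genotypes, centered value 0 when missing.
    """
    x = [[int(v) for v in row] for row in np.asarray(x)]
    n, k = len(x), len(x[0])
    if weights is None:
        weights = [1.0] * k
    p = []
    for j in range(k):
        obs = [x[m][j] for m in range(n) if x[m][j] != MISSING]
        assert obs, "oracle requires every SNP to have a non-missing genotype"
        p.append(sum(obs) / (2.0 * len(obs)))
    z = [
        [0.0 if x[m][j] == MISSING else x[m][j] - 2.0 * p[j] for j in range(k)]
        for m in range(n)
    ]
    denom = 2.0 * sum(pj * (1.0 - pj) for pj in p)
    g = [[0.0] * n for _ in range(n)]
    for m in range(n):
        for q in range(n):
            g[m][q] = sum(z[m][j] * weights[j] * z[q][j] for j in range(k)) / denom
    return g, denom


def random_dosages(rng, n, k, missing_rate=0.0):
    """Random dosage matrix guaranteed polymorphic with >=1 genotype per SNP."""
    while True:
        x = rng.integers(0, 3, size=(n, k)).astype(np.int8)
        if missing_rate > 0.0:
            mask = rng.random((n, k)) < missing_rate
            # never blank out an entire SNP column
            for j in range(k):
                if mask[:, j].all():
                    mask[rng.integers(0, n), j] = False
            x[mask] = MISSING
        obs_ok = all((x[:, j] != MISSING).any() for j in range(k))
        poly = any(len(set(x[:, j][x[:, j] != MISSING].tolist())) > 1 for j in range(k))
        if obs_ok and poly:
            return x


@pytest.fixture
def toy_genotypes():
    """The 2-individual, 2-SNP worked example: X = [[0, 2], [2, 0]]."""
    from seggrm import GenotypeMatrix

    return GenotypeMatrix(["ind1", "ind2"], ["s1", "s2"], np.array([[0, 2], [2, 0]]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
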