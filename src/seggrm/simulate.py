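"""Synthetic genotype data with known structure.

Two generators drive every test of the GRM machinery without any external
dataset:

* :func:`simulate_unrelated` — unrelated individuals under Hardy–Weinberg
  equilibrium: each SNP draws an allele frequency p ~ Uniform(maf_low,
  maf_high) and each genotype is Binomial(2, p), independently.  Under
  observed-frequency centering the resulting GRM has mean diagonal -> 1 and
  mean off-diagonal -> -1/(n-1) as the SNP count grows.

* :func:`simulate_pedigree` — gamete dropping over an explicit pedigree:
  founders are simulated as above and each offspring receives, per locus,
  one allele sampled from each parent.  This yields *known* expected
  relationships (0.5 parent-offspring, 0.5 full sibs) to validate the
  estimator against.

No linkage disequilibrium is simulated: the GRM is a per-SNP sum, so LD
would add no test power.  Genotypes are generated in column blocks directly
into the int8 dosage matrix, keeping generation memory flat in K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import GenotypeMatrix

__all__ = ["SimConfig", "simulate_unrelated", "simulate_pedigree"]

_BLOCK = 4096


@dataclass
class SimConfig:
    """Parameters of the synthetic-genotype generators.

    ``maf_low``/``maf_high`` bound the uniform allele-frequency spectrum
    (defaults 0.05–0.5, a typical post-QC SNP-array spectrum).  ``pedigree``
    is an optional list of ``(child, parent1, parent2)`` index triples;
    parents must precede their children.
    """

    n_individuals: int
    n_snps: int
    maf_low: float = 0.05
    maf_high: float = 0.5
    pedigree: list[tuple[int, int, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("need at least one individual and one SNP")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError(
                f"MAF bounds must satisfy 0 < low <= high <= 0.5; "
                f"got [{self.maf_low}, {self.maf_high}]"
            )
        if self.pedigree is not None:
            seen_children: set[int] = set()
            for child, p1, p2 in self.pedigree:
                for idx in (child, p1, p2):
                    if not (0 <= idx < self.n_individuals):
                        raise ValueError(f"pedigree index {idx} out of range")
                if child in seen_children:
                    raise ValueError(f"individual {child} listed as child twice")
                if p1 >= child or p2 >= child:
                    raise ValueError(
                        f"child {child} listed before parent "
                        f"{max(p1, p2)}: parents must precede children"
                    )
                seen_children.add(child)


def _ids(prefix: str, count: int) -> list[str]:
    width = len(str(count))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(count)]


def _draw_founder_rows(
    rng: np.random.Generator, rows: np.ndarray, p: np.ndarray
) -> None:
    """Fill ``rows`` (m x K int8) with HWE Binomial(2, p) genotypes, blockwise."""
    m, k = rows.shape
    for a in range(0, k, _BLOCK):
        b = min(a + _BLOCK, k)
        rows[:, a:b] = rng.binomial(2, p[a:b], size=(m, b - a)).astype(np.int8)


def simulate_unrelated(cfg: SimConfig) -> GenotypeMatrix:
    """HWE genotypes for unrelated individuals; bit-reproducible per seed."""
    if cfg.pedigree is not None:
        raise ValueError("cfg.pedigree must be None for unrelated simulation")
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_low, cfg.maf_high, cfg.n_snps)
    dosages = np.empty((cfg.n_individuals, cfg.n_snps), dtype=np.int8)
    _draw_founder_rows(rng, dosages, p)
    return GenotypeMatrix(
        _ids("ind", cfg.n_individuals), _ids("snp", cfg.n_snps), dosages
    )


def simulate_pedigree(cfg: SimConfig) -> GenotypeMatrix:
    """Gamete-dropping simulation over ``cfg.pedigree``.

    Founders (individuals never listed as a child) are HWE draws; each child
    genotype is the sum of one allele transmitted by each parent.  For an
    unphased biallelic locus the transmitted allele is Bernoulli(g/2) where
    g is the parent's dosage — exact gamete dropping, since the two alleles
    of a heterozygote are exchangeable.
    """
    if cfg.pedigree is None:
        raise ValueError("cfg.pedigree is required for pedigree simulation")
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_low, cfg.maf_high, cfg.n_snps)
    dosages = np.empty((cfg.n_individuals, cfg.n_snps), dtype=np.int8)
    children = {child for child, _, _ in cfg.pedigree}
    founders = np.array(
        [i for i in range(cfg.n_individuals) if i not in children], dtype=np.intp
    )
    founder_rows = np.empty((len(founders), cfg.n_snps), dtype=np.int8)
    _draw_founder_rows(rng, founder_rows, p)
    dosages[founders] = founder_rows
    for child, p1, p2 in sorted(cfg.pedigree):
        allele1 = rng.random(cfg.n_snps) < dosages[p1] / 2.0
        allele2 = rng.random(cfg.n_snps) < dosages[p2] / 2.0
        dosages[child] = allele1.astype(np.int8) + allele2.astype(np.int8)
    return GenotypeMatrix(
        _ids("ind", cfg.n_individuals), _ids("snp", cfg.n_snps), dosages
    )
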