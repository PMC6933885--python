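"""One-pass genomic relationship matrix (GRM) estimation.

The VanRaden estimator: with Z the frequency-centered dosage matrix
(z_mj = x_mj - 2 p_j),

    G = Z Z' / (2 * sum_j p_j (1 - p_j))

and its SNP-weighted variant G = Z D Z' with D = diag(d_j), d_j >= 0, over
the *same unweighted* denominator.  Monomorphic SNPs contribute zero to both
numerator and denominator and are retained so SNP counts match the input.

The one-pass path here is also the oracle against which the segment-wise
(out-of-core) path in :mod:`seggrm.chunking` is verified: the two are
algebraically identical, differing only in summation grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AlignmentError, DenominatorZeroError, WeightError
from .genotype_io import AlleleFrequencies, CenteredMatrix

__all__ = ["SnpWeights", "Grm", "grm_full", "grm_weighted", "read_weights"]


@dataclass
class SnpWeights:
    """Per-SNP nonnegative weights: the diagonal of D in G = Z D Z'."""

    snp_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        d = np.asarray(self.d, dtype=np.float64)
        if d.ndim != 1 or len(d) != len(self.snp_ids):
            raise WeightError("weights must be 1-D and aligned with snp_ids")
        if np.any(d < 0.0):
            j = int(np.argwhere(d < 0.0)[0, 0])
            raise WeightError(f"negative weight {d[j]} for SNP {self.snp_ids[j]!r}")
        self.d = d

    def slice_snps(self, start: int, end: int) -> "SnpWeights":
        return SnpWeights(self.snp_ids[start:end], self.d[start:end])


@dataclass
class Grm:
    """Symmetric n x n genomic relationship matrix with provenance.

    ``n_snps_used`` and ``denominator`` are ``None`` for matrices read back
    from a dialect that does not carry them.
    """

    individual_ids: list[str]
    matrix: np.ndarray
    n_snps_used: int | None = None
    denominator: float | None = None

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        m = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.individual_ids)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} individuals")
        if not np.array_equal(m, m.T):
            raise ValueError("GRM must be exactly symmetric")
        if self.denominator is not None and not self.denominator > 0:
            raise DenominatorZeroError(
                f"GRM denominator must be positive, got {self.denominator}"
            )
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.individual_ids)


def _syrk(z: np.ndarray) -> np.ndarray:
    """Z Z' via a BLAS rank-k update on the lower triangle, then mirrored.

    Passing ``z.T`` (F-contiguous when z is C-contiguous) with ``trans=1``
    avoids copying the matrix into Fortran order.
    """
    from scipy.linalg.blas import dsyrk

    a = np.ascontiguousarray(z, dtype=np.float64)
    c = dsyrk(1.0, a.T, trans=1, lower=1)
    lower = np.tril(c)
    return lower + np.tril(c, -1).T


def _denominator(freqs: AlleleFrequencies) -> float:
    het = freqs.p * (1.0 - freqs.p)
    return 2.0 * float(np.sum(het))


def grm_full(z: CenteredMatrix, freqs: AlleleFrequencies) -> Grm:
    """One-pass VanRaden GRM: G = Z Z' / (2 * sum p_j (1 - p_j)).

    Sums run over all K SNPs including monomorphic ones, which contribute
    zero to numerator and denominator alike.

    Raises
    ------
    AlignmentError
        ``z`` and ``freqs`` do not describe the same ordered SNP list.
    DenominatorZeroError
        Every SNP is monomorphic (denominator would be zero).
    """
    if freqs.snp_ids != z.snp_ids:
        raise AlignmentError("frequencies are not aligned with the centered matrix")
    denom = _denominator(freqs)
    if denom <= 0.0:
        raise DenominatorZeroError(
            "all SNPs are monomorphic: 2 * sum p(1-p) = 0, no GRM can be formed"
        )
    g = _syrk(z.z) / denom
    return Grm(list(z.individual_ids), g, n_snps_used=z.n_snps, denominator=denom)


def grm_weighted(z: CenteredMatrix, freqs: AlleleFrequencies, w: SnpWeights) -> Grm:
    """SNP-weighted GRM: G = Z D Z' / (2 * sum p_j (1 - p_j)).

    The denominator is deliberately unweighted; consequently scaling all
    weights by c > 0 scales every entry of G by c.  With unit weights the
    result equals :func:`grm_full` to machine precision.
    """
    if freqs.snp_ids != z.snp_ids:
        raise AlignmentError("frequencies are not aligned with the centered matrix")
    if w.snp_ids != z.snp_ids:
        raise WeightError("weights are not aligned with the centered matrix")
    denom = _denominator(freqs)
    if denom <= 0.0:
        raise DenominatorZeroError(
            "all SNPs are monomorphic: 2 * sum p(1-p) = 0, no GRM can be formed"
        )
    zw = z.z * np.sqrt(w.d)  # Z D Z' == (Z sqrt(D)) (Z sqrt(D))' since d_j >= 0
    g = _syrk(zw) / denom
    return Grm(list(z.individual_ids), g, n_snps_used=z.n_snps, denominator=denom)


def read_weights(path: str | Path, snp_ids: Sequence[str]) -> SnpWeights:
    """Read a whitespace-delimited ``snp_id weight`` file aligned to ``snp_ids``.

    Every SNP in ``snp_ids`` must appear — silently defaulting absent weights
    would hide file mismatches.
    """
    path = Path(path)
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise WeightError(f"{path}:{lineno}: expected 'snp_id weight'")
            snp = parts[0]
            if snp in table:
                raise WeightError(f"{path}:{lineno}: duplicate SNP {snp!r}")
            try:
                weight = float(parts[1])
            except ValueError as exc:
                raise WeightError(
                    f"{path}:{lineno}: non-numeric weight {parts[1]!r}"
                ) from exc
            if weight < 0.0:
                raise WeightError(
                    f"{path}:{lineno}: negative weight {weight} for SNP {snp!r}"
                )
            table[snp] = weight
    missing = [s for s in snp_ids if s not in table]
    if missing:
        raise WeightError(
            f"{path}: no weight for SNP {missing[0]!r}"
            + (f" (and {len(missing) - 1} more)" if len(missing) > 1 else "")
        )
    d = np.array([table[s] for s in snp_ids], dtype=np.float64)
    return SnpWeights([str(s) for s in snp_ids], d)
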