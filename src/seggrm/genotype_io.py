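"""Genotype input/output, allele frequencies, and centering.

The canonical in-memory representation is an individuals x SNPs matrix of
additive allele dosages (0, 1, 2) stored as ``int8`` with ``-1`` marking a
missing genotype.  Three text formats are read: VCF (biallelic GT records,
dosage = ALT-allele count), PLINK additive-coded ``.raw`` tables, and a plain
whitespace/TAB matrix with a header row of SNP IDs and a leading column of
individual IDs.

Centering subtracts twice the allele frequency from each dosage
(``z_mj = x_mj - 2 p_j``), the VanRaden parameterization in which the
cross-product of centered rows measures genomic relationship.  Missing
genotypes are mean-imputed, i.e. set to ``z = 0`` after centering, which
leaves both the numerator and the denominator of the estimator well defined
without dropping individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DuplicateIdError,
    FrequencyError,
    GenotypeParseError,
)

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "AlleleFrequencies",
    "CenteredMatrix",
    "read_genotypes",
    "allele_frequencies",
    "read_frequencies",
    "center",
    "write_tsv",
    "write_vcf",
]

log = logging.getLogger(__name__)

#: Sentinel for a missing genotype in the int8 dosage matrix.
MISSING: int = -1

# Column-block width used whenever a full-matrix pass would otherwise
# materialize temporaries comparable in size to the dosage matrix itself.
_BLOCK = 8192

FreqSource = Literal["observed", "external"]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdError(f"duplicate {kind} ID {i!r}")
        seen.add(i)


def _column_blocks(n_cols: int, block: int = _BLOCK):
    for start in range(0, n_cols, block):
        yield start, min(start + block, n_cols)


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix with individual and SNP identifiers.

    ``dosages`` is n x K ``int8``; every entry is 0, 1, 2, or :data:`MISSING`.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        d = np.asarray(self.dosages)
        if d.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs matrix")
        if not np.issubdtype(d.dtype, np.integer):
            raise ValueError("dosages must be an integer array (int8 canonical)")
        d = d.astype(np.int8, copy=False)
        n, k = d.shape
        if n < 1 or k < 1:
            raise ValueError("need at least one individual and one SNP")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.snp_ids) != k:
            raise ValueError("snp_ids length does not match dosage columns")
        _check_unique(self.individual_ids, "individual")
        _check_unique(self.snp_ids, "SNP")
        # blockwise so validation never allocates O(nK) boolean temporaries
        for a, b in _column_blocks(k):
            blk = d[:, a:b]
            bad = (blk > 2) | ((blk < 0) & (blk != MISSING))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"dosage {int(blk[i, j])} outside {{0,1,2,missing}} at "
                    f"individual {self.individual_ids[int(i)]!r}, "
                    f"SNP {self.snp_ids[int(a + j)]!r}"
                )
        self.dosages = d

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def slice_snps(self, start: int, end: int) -> "GenotypeMatrix":
        """Return the sub-matrix for SNP columns ``[start, end)`` (a view)."""
        if not (0 <= start < end <= self.n_snps):
            raise IndexError(f"SNP range [{start}, {end}) outside [0, {self.n_snps})")
        return GenotypeMatrix(
            self.individual_ids, self.snp_ids[start:end], self.dosages[:, start:end]
        )


@dataclass
class AlleleFrequencies:
    """Per-SNP reference (counted) allele frequency, aligned to a SNP list."""

    snp_ids: list[str]
    p: np.ndarray
    source: FreqSource = "observed"

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        p = np.asarray(self.p, dtype=np.float64)
        if p.ndim != 1 or len(p) != len(self.snp_ids):
            raise ValueError("p must be 1-D and aligned with snp_ids")
        if np.any((p < 0.0) | (p > 1.0)):
            j = int(np.argwhere((p < 0.0) | (p > 1.0))[0, 0])
            raise FrequencyError(
                f"frequency {p[j]} for SNP {self.snp_ids[j]!r} outside [0, 1]"
            )
        if self.source not in ("observed", "external"):
            raise ValueError(f"unknown frequency source {self.source!r}")
        self.p = p

    def slice_snps(self, start: int, end: int) -> "AlleleFrequencies":
        return AlleleFrequencies(self.snp_ids[start:end], self.p[start:end], self.source)


@dataclass
class CenteredMatrix:
    """Frequency-centered dosage matrix Z with z_mj = x_mj - 2 p_j.

    Missing genotypes are represented as exact zeros (mean imputation).
    Every entry lies in [-2, 2].
    """

    individual_ids: list[str]
    snp_ids: list[str]
    z: np.ndarray
    freq_source: FreqSource = "observed"

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        z = np.asarray(self.z, dtype=np.float64)
        if z.ndim != 2 or z.shape != (len(self.individual_ids), len(self.snp_ids)):
            raise ValueError("z shape does not match the ID lists")
        for a, b in _column_blocks(z.shape[1]):
            blk = z[:, a:b]
            if blk.size and (np.min(blk) < -2.0 or np.max(blk) > 2.0):
                raise ValueError("centered entries must lie in [-2, 2]")
        self.z = z

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def n_snps(self) -> int:
        return self.z.shape[1]

    def slice_snps(self, start: int, end: int) -> "CenteredMatrix":
        if not (0 <= start < end <= self.n_snps):
            raise IndexError(f"SNP range [{start}, {end}) outside [0, {self.n_snps})")
        return CenteredMatrix(
            self.individual_ids,
            self.snp_ids[start:end],
            self.z[:, start:end],
            self.freq_source,
        )


# ---------------------------------------------------------------------------
# readers


_TOKEN_MAP = {"0": 0, "1": 1, "2": 2, "NA": MISSING}


def _table_to_dosages(
    raw: np.ndarray, individual_ids: Sequence[str], snp_ids: Sequence[str]
) -> np.ndarray:
    out = np.full(raw.shape, -9, dtype=np.int8)
    for token, value in _TOKEN_MAP.items():
        out[raw == token] = value
    bad = out == -9
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"dosage {raw[i, j]!r} outside {{0,1,2,NA}} at individual "
            f"{individual_ids[int(i)]!r}, SNP {snp_ids[int(j)]!r}"
        )
    return out


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise GenotypeParseError(f"{path}: need an ID column plus at least one SNP")
    individual_ids = df.iloc[:, 0].tolist()
    snp_ids = [str(c) for c in df.columns[1:]]
    if len(individual_ids) == 0:
        raise GenotypeParseError(f"{path}: no individual rows")
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    dosages = _table_to_dosages(raw, individual_ids, snp_ids)
    return GenotypeMatrix(individual_ids, snp_ids, dosages)


_PLINK_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _read_plink_raw(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", header=0, dtype=str, keep_default_na=False)
    cols = [str(c) for c in df.columns]
    if len(cols) < 7 or tuple(cols[:6]) != _PLINK_META_COLS:
        raise GenotypeParseError(
            f"{path}: not PLINK .raw — header must start with "
            + " ".join(_PLINK_META_COLS)
        )
    individual_ids = df["IID"].tolist()
    # SNP column names are kept verbatim (including any counted-allele suffix);
    # stripping after the last underscore would mangle IDs containing '_'.
    snp_ids = cols[6:]
    raw = df.iloc[:, 6:].to_numpy(dtype=object)
    dosages = _table_to_dosages(raw, individual_ids, snp_ids)
    return GenotypeMatrix(individual_ids, snp_ids, dosages)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeParseError(f"{path}: VCF has no sample columns")
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_multiallelic = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multiallelic += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # trailing element is the phased flag
            if len(alleles) == 0 or min(alleles) < 0:
                col[i] = MISSING
            else:
                col[i] = sum(1 for a in alleles if a == 1)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(col)
    if n_multiallelic:
        log.warning(
            "%s: skipped %d multiallelic record(s); only biallelic SNPs are used",
            path,
            n_multiallelic,
        )
    if not columns:
        raise GenotypeParseError(f"{path}: no biallelic SNP records")
    dosages = np.stack(columns, axis=1)
    return GenotypeMatrix(samples, snp_ids, dosages)


def read_genotypes(
    path: str | Path, format: Literal["vcf", "plink_raw", "tsv"]
) -> GenotypeMatrix:
    """Read a genotype file into the canonical dosage representation.

    Parameters
    ----------
    path
        Input file.  VCF may be plain or bgzipped.
    format
        ``"vcf"`` (dosage = ALT-allele count per GT, ``./.`` missing),
        ``"plink_raw"`` (PLINK additive coding, ``NA`` missing), or
        ``"tsv"`` (header ``ID snp1 snp2 ...``, one row per individual).

    Raises
    ------
    GenotypeParseError
        Unknown format, unparseable file, or out-of-range dosage.
    DuplicateIdError
        A repeated individual or SNP identifier.
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeParseError(f"genotype file not found: {path}")
    if format == "tsv":
        return _read_tsv(path)
    if format == "plink_raw":
        return _read_plink_raw(path)
    if format == "vcf":
        return _read_vcf(path)
    raise GenotypeParseError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# frequencies and centering


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """Observed per-SNP allele frequency over non-missing genotypes.

    ``p_j = (sum of non-missing dosages at j) / (2 * non-missing count at j)``.

    Raises
    ------
    FrequencyError
        If some SNP has every genotype missing.
    """
    k = g.n_snps
    p = np.empty(k, dtype=np.float64)
    for a, b in _column_blocks(k):
        blk = g.dosages[:, a:b]
        mask = blk != MISSING
        counts = mask.sum(axis=0, dtype=np.int64)
        if np.any(counts == 0):
            j = int(np.argwhere(counts == 0)[0, 0]) + a
            raise FrequencyError(f"SNP {g.snp_ids[j]!r} has all genotypes missing")
        sums = np.where(mask, blk, 0).sum(axis=0, dtype=np.int64)
        p[a:b] = sums / (2.0 * counts)
    return AlleleFrequencies(list(g.snp_ids), p, source="observed")


def read_frequencies(path: str | Path, snp_ids: Sequence[str]) -> AlleleFrequencies:
    """Read an external allele-frequency file and align it to ``snp_ids``.

    The file is whitespace-delimited ``snp_id frequency`` lines.  Every
    requested SNP must appear; frequencies must lie in [0, 1].
    """
    path = Path(path)
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise FrequencyError(f"{path}:{lineno}: expected 'snp_id frequency'")
            snp = parts[0]
            if snp in table:
                raise FrequencyError(f"{path}:{lineno}: duplicate SNP {snp!r}")
            try:
                freq = float(parts[1])
            except ValueError as exc:
                raise FrequencyError(
                    f"{path}:{lineno}: non-numeric frequency {parts[1]!r}"
                ) from exc
            if not (0.0 <= freq <= 1.0):
                raise FrequencyError(
                    f"{path}:{lineno}: frequency {freq} for SNP {snp!r} outside [0, 1]"
                )
            table[snp] = freq
    missing = [s for s in snp_ids if s not in table]
    if missing:
        raise FrequencyError(
            f"{path}: no frequency for SNP {missing[0]!r}"
            + (f" (and {len(missing) - 1} more)" if len(missing) > 1 else "")
        )
    p = np.array([table[s] for s in snp_ids], dtype=np.float64)
    return AlleleFrequencies([str(s) for s in snp_ids], p, source="external")


def center(g: GenotypeMatrix, freqs: AlleleFrequencies) -> CenteredMatrix:
    """Center dosages by twice the allele frequency; missing entries become 0.

    Raises
    ------
    AlignmentError
        If ``freqs`` is not aligned one-to-one with ``g.snp_ids``.
    """
    if freqs.snp_ids != g.snp_ids:
        raise AlignmentError("allele frequencies are not aligned with the genotypes")
    n, k = g.dosages.shape
    z = np.empty((n, k), dtype=np.float64)
    for a, b in _column_blocks(k):
        blk = g.dosages[:, a:b]
        z[:, a:b] = np.where(blk == MISSING, 0.0, blk - 2.0 * freqs.p[a:b])
    return CenteredMatrix(list(g.individual_ids), list(g.snp_ids), z, freqs.source)


# ---------------------------------------------------------------------------
# writers (TSV dialect read back by read_genotypes; minimal VCF for
# end-to-end format tests)


def write_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV genotype dialect (``ID`` header, ``NA`` for missing)."""
    with open(path, "w") as fh:
        fh.write("ID\t" + "\t".join(g.snp_ids) + "\n")
        for i, ind in enumerate(g.individual_ids):
            row = ["NA" if d == MISSING else str(int(d)) for d in g.dosages[i]]
            fh.write(ind + "\t" + "\t".join(row) + "\n")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal single-chromosome VCF 4.2 with GT fields only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j, snp in enumerate(g.snp_ids):
            gts = "\t".join(_GT_CODE[int(d)] for d in g.dosages[:, j])
            fh.write(f"1\t{j + 1}\t{snp}\tA\tG\t.\t.\t.\tGT\t{gts}\n")
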