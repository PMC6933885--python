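"""GRM output in interoperable dialects.

Three dialects cover downstream GBLUP tooling:

``text_long``
    Plain text ``id_i id_j value`` lines for the lower triangle including
    the diagonal, in 1-based pair order (i >= j), 10 significant digits.
``gcta_gz``
    GCTA gzipped-text GRM: lines ``i j n_snps G_ij`` (1-based indices) in
    ``<stem>.grm.gz`` plus a ``<stem>.grm.id`` sidecar of ``fid iid`` pairs
    (family ID mirrored from the individual ID).
``gcta_bin``
    GCTA binary GRM: ``<stem>.grm.bin`` lower triangle (row-major, i >= j)
    as little-endian 32-bit floats, ``<stem>.grm.N.bin`` with the SNP count
    per pair as 32-bit floats, and the same ``.grm.id`` sidecar.

The in-memory and segment-summary representations stay 64-bit; only the
GCTA binary dialect downcasts, matching the GCTA convention.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import GrmFormatError
from .grm_core import Grm

__all__ = ["GrmOutputSpec", "write_grm", "read_grm"]

Dialect = Literal["text_long", "gcta_gz", "gcta_bin"]
_DIALECTS = ("text_long", "gcta_gz", "gcta_bin")

# GCTA-style indices are written as plain integers but kept within the range
# 32-bit tools can read back.
_MAX_N = 2**31 - 1


@dataclass
class GrmOutputSpec:
    """Where and how to write a GRM: dialect, path stem, binary float width."""

    dialect: Dialect
    stem: str | Path
    precision: Literal[32] = 32

    def __post_init__(self) -> None:
        if self.dialect not in _DIALECTS:
            raise GrmFormatError(
                f"unknown GRM dialect {self.dialect!r}; expected one of {_DIALECTS}"
            )
        if self.precision != 32:
            raise GrmFormatError("binary GRM output supports 32-bit floats only")
        self.stem = Path(self.stem)


def _tril_pairs(n: int):
    for i in range(n):
        for j in range(i + 1):
            yield i, j


def _write_id_file(g: Grm, path: Path) -> None:
    with open(path, "w") as fh:
        for iid in g.individual_ids:
            fh.write(f"{iid}\t{iid}\n")


def write_grm(g: Grm, spec: GrmOutputSpec) -> list[Path]:
    """Write ``g`` in the requested dialect; returns the paths produced."""
    if g.n > _MAX_N:
        raise GrmFormatError(f"{g.n} individuals exceed the dialect's index width")
    stem = Path(spec.stem)
    n_snps = g.n_snps_used if g.n_snps_used is not None else 0
    if spec.dialect == "text_long":
        path = stem.with_name(stem.name + ".grm.txt")
        with open(path, "w") as fh:
            for i, j in _tril_pairs(g.n):
                fh.write(
                    f"{g.individual_ids[i]}\t{g.individual_ids[j]}\t"
                    f"{g.matrix[i, j]:.10g}\n"
                )
        return [path]
    if spec.dialect == "gcta_gz":
        gz_path = stem.with_name(stem.name + ".grm.gz")
        id_path = stem.with_name(stem.name + ".grm.id")
        with gzip.open(gz_path, "wt") as fh:
            for i, j in _tril_pairs(g.n):
                fh.write(f"{i + 1}\t{j + 1}\t{n_snps}\t{g.matrix[i, j]:.10g}\n")
        _write_id_file(g, id_path)
        return [gz_path, id_path]
    # gcta_bin
    bin_path = stem.with_name(stem.name + ".grm.bin")
    nbin_path = stem.with_name(stem.name + ".grm.N.bin")
    id_path = stem.with_name(stem.name + ".grm.id")
    tri = g.matrix[np.tril_indices(g.n)].astype("<f4")
    tri.tofile(bin_path)
    np.full(tri.shape, n_snps, dtype="<f4").tofile(nbin_path)
    _write_id_file(g, id_path)
    return [bin_path, nbin_path, id_path]


def _mirror(tri: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n), dtype=np.float64)
    m[np.tril_indices(n)] = tri
    return m + np.tril(m, -1).T


def _read_id_file(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise GrmFormatError(f"{path}: expected 'fid iid' lines")
            ids.append(parts[1])
    if not ids:
        raise GrmFormatError(f"{path}: empty ID file")
    return ids


def _check_triangle(n_pairs: int, n_ids: int, what: str) -> None:
    if n_pairs != n_ids * (n_ids + 1) // 2:
        raise GrmFormatError(
            f"{what}: {n_pairs} pairs inconsistent with {n_ids} individuals "
            f"(expected {n_ids * (n_ids + 1) // 2})"
        )


def read_grm(stem: str | Path, dialect: Dialect) -> Grm:
    """Read a GRM previously written by :func:`write_grm`.

    Symmetry is restored by mirroring the stored triangle.  Dialects that do
    not carry the SNP count or denominator return ``None`` for those fields.
    """
    stem = Path(stem)
    if dialect == "text_long":
        path = stem.with_name(stem.name + ".grm.txt")
        ids: list[str] = []
        values: list[float] = []
        pairs: list[tuple[str, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 3:
                    raise GrmFormatError(f"{path}:{lineno}: expected 'id_i id_j value'")
                pairs.append((parts[0], parts[1]))
                values.append(float(parts[2]))
                if parts[0] == parts[1]:
                    ids.append(parts[0])
        _check_triangle(len(values), len(ids), str(path))
        index = {iid: i for i, iid in enumerate(ids)}
        m = np.zeros((len(ids), len(ids)), dtype=np.float64)
        for (a, b), v in zip(pairs, values):
            if a not in index or b not in index:
                raise GrmFormatError(f"{path}: pair ({a!r}, {b!r}) has unknown ID")
            m[index[a], index[b]] = v
        m = np.tril(m) + np.tril(m, -1).T
        return Grm(ids, m)
    if dialect == "gcta_gz":
        gz_path = stem.with_name(stem.name + ".grm.gz")
        ids = _read_id_file(stem.with_name(stem.name + ".grm.id"))
        tri_vals: list[float] = []
        n_snps = None
        with gzip.open(gz_path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 4:
                    raise GrmFormatError(f"{gz_path}:{lineno}: expected 'i j n value'")
                tri_vals.append(float(parts[3]))
                n_snps = int(float(parts[2]))
        _check_triangle(len(tri_vals), len(ids), str(gz_path))
        return Grm(
            ids,
            _mirror(np.array(tri_vals), len(ids)),
            n_snps_used=n_snps if n_snps else None,
        )
    if dialect == "gcta_bin":
        bin_path = stem.with_name(stem.name + ".grm.bin")
        ids = _read_id_file(stem.with_name(stem.name + ".grm.id"))
        raw = np.fromfile(bin_path, dtype="<f4")
        _check_triangle(len(raw), len(ids), str(bin_path))
        n_snps = None
        nbin_path = stem.with_name(stem.name + ".grm.N.bin")
        if nbin_path.exists():
            nvals = np.fromfile(nbin_path, dtype="<f4")
            _check_triangle(len(nvals), len(ids), str(nbin_path))
            if len(nvals) and nvals[0] > 0:
                n_snps = int(nvals[0])
        return Grm(
            ids,
            _mirror(raw.astype(np.float64), len(ids)),
            n_snps_used=n_snps,
        )
    raise GrmFormatError(f"unknown GRM dialect {dialect!r}; expected one of {_DIALECTS}")
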