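"""Segment-wise (out-of-core) GRM construction.

The VanRaden estimator is a ratio of two sums over SNPs, and both sums are
additive: splitting the K SNPs into d disjoint segments, computing for
segment s the numerator cross-product D_s = Z_s Z_s' (n x n) and the
denominator contribution N_s = sum_{j in s} p_j (1 - p_j), and then forming

    G = (sum_s D_s) / (2 * sum_s N_s)

is *exactly* the one-pass computation with the terms regrouped.  Peak memory
for the segment step is therefore one n x n accumulator plus one segment of
genotypes, independent of K — which is what makes whole-genome GRMs feasible
when n and K are both large.

Summaries are persisted in the binary "ICGRM1" container (64-bit float
payload, CRC-32 checksum) so segments can be computed by independent
processes, possibly on different machines, and integrated later.  Segments
are contiguous index ranges over the input SNP order; chromosome-aware
planning is out of scope (any scheduler can drive per-chromosome runs by
passing explicit ranges).

Combining a *subset* of segments is legal — it yields the GRM of that subset
of the genome (e.g. a per-chromosome GRM) — and raises only a warning for
coverage gaps; overlapping segments double-count SNPs and are always an
error.
"""

from __future__ import annotations

import struct
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    CorruptSummaryError,
    DenominatorZeroError,
    IncompatibleSummariesError,
    UnsupportedVersionError,
)
from .genotype_io import AlleleFrequencies, CenteredMatrix
from .grm_core import Grm, SnpWeights, _syrk

__all__ = [
    "SegmentPlan",
    "SegmentSummary",
    "CoverageGapWarning",
    "plan_segments",
    "segment_summary",
    "write_summary",
    "read_summary",
    "peek_summary_range",
    "combine_summaries",
    "combine_summary_files",
]

MAGIC = b"ICGRM1\x00"
FORMAT_VERSION = 1

_FLAG_WEIGHTED = 0x01
_FLAG_EXTERNAL_FREQ = 0x02

# fixed-size header that follows the magic byte string
_HEAD = struct.Struct("<BBIIQQ")  # version, flags, n, k_s, start, end


class CoverageGapWarning(UserWarning):
    """Combined segments do not cover a contiguous SNP range."""


@dataclass
class SegmentPlan:
    """Disjoint, sorted half-open SNP index ranges covering [0, K) exactly."""

    total_snps: int
    boundaries: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.boundaries = [(int(a), int(b)) for a, b in self.boundaries]
        prev = 0
        for a, b in self.boundaries:
            if a != prev or b <= a:
                raise ValueError("segment ranges must be sorted, non-empty, contiguous")
            prev = b
        if prev != self.total_snps:
            raise ValueError("segment ranges must cover [0, K) exactly")

    @property
    def d(self) -> int:
        return len(self.boundaries)


def plan_segments(total_snps: int, n_parts: int) -> SegmentPlan:
    """Split K SNPs into ``n_parts`` contiguous segments of near-equal size.

    Sizes differ by at most one; the first ``K mod d`` segments take the
    extra SNP.  Deterministic.
    """
    k, d = int(total_snps), int(n_parts)
    if d < 1 or d > k:
        raise ValueError(f"part count must satisfy 1 <= d <= K; got d={d}, K={k}")
    base, extra = divmod(k, d)
    boundaries = []
    start = 0
    for s in range(d):
        size = base + (1 if s < extra else 0)
        boundaries.append((start, start + size))
        start += size
    return SegmentPlan(k, boundaries)


@dataclass(eq=False)
class SegmentSummary:
    """Additive per-segment GRM statistics: numerator D_s and denominator N_s.

    ``numerator`` is the n x n symmetric cross-product Z_s Z_s' (or
    Z_s D_s^w Z_s' when ``weighted``); ``denominator`` is
    N_s = sum_{j in segment} p_j (1 - p_j), unweighted in both modes.
    """

    individual_ids: list[str]
    start: int
    end: int
    snp_id_first: str
    snp_id_last: str
    numerator: np.ndarray
    denominator: float
    weighted: bool
    freq_source: str

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.start, self.end = int(self.start), int(self.end)
        num = np.asarray(self.numerator, dtype=np.float64)
        n = len(self.individual_ids)
        if num.shape != (n, n):
            raise ValueError("numerator must be n x n for the stated individuals")
        if not np.array_equal(num, num.T):
            raise ValueError("numerator must be exactly symmetric")
        if self.n_snps < 1:
            raise ValueError("segment must contain at least one SNP")
        if self.denominator < 0.0:
            raise ValueError("segment denominator N_s cannot be negative")
        if self.freq_source not in ("observed", "external"):
            raise ValueError(f"unknown frequency source {self.freq_source!r}")
        self.denominator = float(self.denominator)
        self.weighted = bool(self.weighted)
        self.numerator = num

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return self.end - self.start


def segment_summary(
    z: CenteredMatrix,
    freqs: AlleleFrequencies,
    weights: SnpWeights | None = None,
    *,
    segment_range: tuple[int, int] | None = None,
) -> SegmentSummary:
    """Compute D_s and N_s for one segment.

    ``z``, ``freqs`` and (optionally) ``weights`` are the segment's own data,
    already restricted to its SNPs; ``segment_range`` records which global
    SNP index range [start, end) they cover (defaults to ``(0, k_s)``).
    """
    if freqs.snp_ids != z.snp_ids:
        raise AlignmentError("frequencies are not aligned with the segment")
    if weights is not None and weights.snp_ids != z.snp_ids:
        raise AlignmentError("weights are not aligned with the segment")
    start, end = segment_range if segment_range is not None else (0, z.n_snps)
    if end - start != z.n_snps or start < 0:
        raise AlignmentError(
            f"segment range [{start}, {end}) does not match {z.n_snps} SNPs"
        )
    zmat = z.z if weights is None else z.z * np.sqrt(weights.d)
    numerator = _syrk(zmat)
    denominator = float(np.sum(freqs.p * (1.0 - freqs.p)))
    return SegmentSummary(
        individual_ids=list(z.individual_ids),
        start=start,
        end=end,
        snp_id_first=z.snp_ids[0],
        snp_id_last=z.snp_ids[-1],
        numerator=numerator,
        denominator=denominator,
        weighted=weights is not None,
        freq_source=z.freq_source,
    )


def iter_segment_summaries(
    z: CenteredMatrix,
    freqs: AlleleFrequencies,
    plan: SegmentPlan,
    weights: SnpWeights | None = None,
) -> Iterator[SegmentSummary]:
    """Yield the summary of every segment of ``plan`` over full-genome inputs."""
    if plan.total_snps != z.n_snps:
        raise AlignmentError("segment plan does not match the SNP count")
    for a, b in plan.boundaries:
        yield segment_summary(
            z.slice_snps(a, b),
            freqs.slice_snps(a, b),
            weights.slice_snps(a, b) if weights is not None else None,
            segment_range=(a, b),
        )


# ---------------------------------------------------------------------------
# ICGRM1 serialization


def _encode_str(s: str) -> bytes:
    raw = s.encode("utf-8")
    if len(raw) > 0xFFFF:
        raise ValueError("identifier too long for the summary format")
    return struct.pack("<H", len(raw)) + raw


def write_summary(summary: SegmentSummary, path: str | Path) -> None:
    """Write one segment summary in the ICGRM1 container (lossless)."""
    n = summary.n
    flags = (_FLAG_WEIGHTED if summary.weighted else 0) | (
        _FLAG_EXTERNAL_FREQ if summary.freq_source == "external" else 0
    )
    parts = [
        _HEAD.pack(FORMAT_VERSION, flags, n, summary.n_snps, summary.start, summary.end),
        _encode_str(summary.snp_id_first),
        _encode_str(summary.snp_id_last),
    ]
    ids_blob = "\n".join(summary.individual_ids).encode("utf-8")
    parts.append(struct.pack("<I", len(ids_blob)))
    parts.append(ids_blob)
    parts.append(struct.pack("<d", summary.denominator))
    tri = summary.numerator[np.tril_indices(n)]  # row-major lower triangle, i >= j
    parts.append(np.ascontiguousarray(tri, dtype="<f8").tobytes())
    payload = b"".join(parts)
    checksum = struct.pack("<I", zlib.crc32(payload) & 0xFFFFFFFF)
    Path(path).write_bytes(MAGIC + payload + checksum)


class _Cursor:
    """Bounds-checked reader over the summary byte buffer."""

    def __init__(self, data: bytes, path: Path):
        self.data = data
        self.pos = 0
        self.path = path

    def take(self, nbytes: int) -> bytes:
        if self.pos + nbytes > len(self.data):
            raise CorruptSummaryError(f"{self.path}: truncated summary file")
        out = self.data[self.pos : self.pos + nbytes]
        self.pos += nbytes
        return out


def _check_magic_version(data: bytes, path: Path) -> None:
    if len(data) < len(MAGIC) + 1 or data[: len(MAGIC)] != MAGIC:
        raise CorruptSummaryError(f"{path}: not an ICGRM1 summary file (bad magic)")
    version = data[len(MAGIC)]
    if version != FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"{path}: summary format version {version}, "
            f"this reader supports version {FORMAT_VERSION}"
        )


def peek_summary_range(path: str | Path) -> tuple[int, int]:
    """Read only the [start, end) range from a summary file's fixed header."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(len(MAGIC) + _HEAD.size)
    _check_magic_version(head, path)
    if len(head) < len(MAGIC) + _HEAD.size:
        raise CorruptSummaryError(f"{path}: truncated summary file")
    _, _, _, _, start, end = _HEAD.unpack_from(head, len(MAGIC))
    return int(start), int(end)


def read_summary(path: str | Path) -> SegmentSummary:
    """Read an ICGRM1 summary; verifies magic, version, length and checksum."""
    path = Path(path)
    data = Path(path).read_bytes()
    _check_magic_version(data, path)
    if len(data) < len(MAGIC) + _HEAD.size + 4:
        raise CorruptSummaryError(f"{path}: truncated summary file")
    payload, stored = data[len(MAGIC) : -4], data[-4:]
    if zlib.crc32(payload) & 0xFFFFFFFF != struct.unpack("<I", stored)[0]:
        raise CorruptSummaryError(f"{path}: checksum mismatch (corrupt summary)")
    cur = _Cursor(payload, path)
    version, flags, n, k_s, start, end = _HEAD.unpack(cur.take(_HEAD.size))
    if end - start != k_s:
        raise CorruptSummaryError(f"{path}: inconsistent segment range metadata")
    (len_first,) = struct.unpack("<H", cur.take(2))
    snp_first = cur.take(len_first).decode("utf-8")
    (len_last,) = struct.unpack("<H", cur.take(2))
    snp_last = cur.take(len_last).decode("utf-8")
    (ids_len,) = struct.unpack("<I", cur.take(4))
    ids = cur.take(ids_len).decode("utf-8").split("\n")
    if len(ids) != n:
        raise CorruptSummaryError(f"{path}: individual-ID block does not match n={n}")
    (denominator,) = struct.unpack("<d", cur.take(8))
    n_tri = n * (n + 1) // 2
    tri = np.frombuffer(cur.take(8 * n_tri), dtype="<f8")
    if cur.pos != len(payload):
        raise CorruptSummaryError(f"{path}: trailing bytes after numerator payload")
    numerator = np.zeros((n, n), dtype=np.float64)
    numerator[np.tril_indices(n)] = tri
    numerator = numerator + np.tril(numerator, -1).T
    return SegmentSummary(
        individual_ids=ids,
        start=start,
        end=end,
        snp_id_first=snp_first,
        snp_id_last=snp_last,
        numerator=numerator,
        denominator=denominator,
        weighted=bool(flags & _FLAG_WEIGHTED),
        freq_source="external" if flags & _FLAG_EXTERNAL_FREQ else "observed",
    )


# ---------------------------------------------------------------------------
# integration


def _accumulate(summaries: Iterable[SegmentSummary]) -> Grm:
    """Sum summaries already sorted by segment start; validate compatibility."""
    first: SegmentSummary | None = None
    prev_end = 0
    numerator_sum: np.ndarray | None = None
    denominator_sum = 0.0
    n_snps_total = 0
    for s in summaries:
        if first is None:
            first = s
            if s.start > 0:
                warnings.warn(
                    f"segments start at SNP index {s.start}, not 0: the result is "
                    "the GRM of a genome subset",
                    CoverageGapWarning,
                    stacklevel=3,
                )
        else:
            if len(s.individual_ids) != len(first.individual_ids):
                raise IncompatibleSummariesError(
                    f"summaries disagree on individual count: "
                    f"{len(first.individual_ids)} vs {len(s.individual_ids)}"
                )
            for i, (a, b) in enumerate(zip(first.individual_ids, s.individual_ids)):
                if a != b:
                    raise IncompatibleSummariesError(
                        f"summaries disagree on individual order at position {i}: "
                        f"{a!r} vs {b!r}"
                    )
            if s.weighted != first.weighted:
                raise IncompatibleSummariesError(
                    "cannot combine weighted with unweighted summaries"
                )
            if s.freq_source != first.freq_source:
                raise IncompatibleSummariesError(
                    "cannot combine summaries with mismatched allele-frequency "
                    f"sources ({first.freq_source!r} vs {s.freq_source!r})"
                )
            if s.start < prev_end:
                raise IncompatibleSummariesError(
                    f"segment [{s.start}, {s.end}) overlaps a previous segment "
                    f"ending at {prev_end}: SNPs would be double-counted"
                )
            if s.start > prev_end:
                warnings.warn(
                    f"gap between SNP indices {prev_end} and {s.start}: the result "
                    "is the GRM of a genome subset",
                    CoverageGapWarning,
                    stacklevel=3,
                )
        if numerator_sum is None:
            numerator_sum = s.numerator.copy()
        else:
            numerator_sum += s.numerator
        denominator_sum += s.denominator
        n_snps_total += s.n_snps
        prev_end = s.end
    if first is None or numerator_sum is None:
        raise IncompatibleSummariesError("need at least one segment summary")
    denom = 2.0 * denominator_sum
    if denom <= 0.0:
        raise DenominatorZeroError(
            "combined denominator 2 * sum N_s is zero: all SNPs monomorphic"
        )
    return Grm(
        list(first.individual_ids),
        numerator_sum / denom,
        n_snps_used=n_snps_total,
        denominator=denom,
    )


def combine_summaries(summaries: Sequence[SegmentSummary]) -> Grm:
    """Integrate segment summaries into the whole-genome GRM.

    G = (sum_s D_s) / (2 * sum_s N_s).  Summaries are processed in order of
    segment start, so the result is invariant to the order they are given in
    (bit-identical, not merely close).
    """
    return _accumulate(sorted(summaries, key=lambda s: (s.start, s.end)))


def combine_summary_files(paths: Sequence[str | Path]) -> Grm:
    """Streaming combine: reads one ICGRM1 file at a time, in segment order.

    Peak memory is the n x n accumulator plus a single summary, regardless of
    how many segment files are integrated.
    """
    if not paths:
        raise IncompatibleSummariesError("need at least one segment summary file")
    ordered = sorted(paths, key=lambda p: peek_summary_range(p))
    return _accumulate(read_summary(p) for p in ordered)
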