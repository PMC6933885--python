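"""Segment planning, per-segment summaries, serialization, and integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seggrm as sg
from seggrm.chunking import CoverageGapWarning, peek_summary_range
from seggrm.errors import (
    CorruptSummaryError,
    DenominatorZeroError,
    IncompatibleSummariesError,
    UnsupportedVersionError,
)

from conftest import random_dosages


def _pipeline(x):
    n, k = np.asarray(x).shape
    g = sg.GenotypeMatrix(
        [f"i{m}" for m in range(n)], [f"s{j}" for j in range(k)], np.asarray(x)
    )
    f = sg.allele_frequencies(g)
    return sg.center(g, f), f


# ---------------------------------------------------------------------------
# planning


@pytest.mark.parametrize(
    "k, d, expected",
    [
        (10, 3, [(0, 4), (4, 7), (7, 10)]),
        (10, 1, [(0, 10)]),
        (5, 5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]),
    ],
)
def test_plan_examples(k, d, expected):
    assert sg.plan_segments(k, d).boundaries == expected


@pytest.mark.parametrize("k, d", [(10, 0), (10, 11), (10, -1)])
def test_plan_rejects_bad_part_counts(k, d):
    with pytest.raises(ValueError):
        sg.plan_segments(k, d)


@given(k=st.integers(1, 500), d=st.integers(1, 500))
@settings(max_examples=80, derandomize=True, deadline=None)
def test_plan_is_balanced_partition(k, d):
    if d > k:
        d = k
    plan = sg.plan_segments(k, d)
    sizes = [b - a for a, b in plan.boundaries]
    assert sum(sizes) == k
    assert plan.d == d
    assert max(sizes) - min(sizes) <= 1
    # extras assigned from the front
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# segment summaries


def test_single_snp_segment_hand_oracle(toy_genotypes):
    """Segment [0,1) of X=[[0,2],[2,0]]: D_s=[[1,-1],[-1,1]], N_s=0.25."""
    f = sg.allele_frequencies(toy_genotypes)
    z = sg.center(toy_genotypes, f)
    s = sg.segment_summary(
        z.slice_snps(0, 1), f.slice_snps(0, 1), segment_range=(0, 1)
    )
    np.testing.assert_allclose(s.numerator, [[1.0, -1.0], [-1.0, 1.0]], atol=0)
    assert s.denominator == pytest.approx(0.25, abs=0)
    assert (s.start, s.end) == (0, 1)
    assert s.snp_id_first == s.snp_id_last == "s1"


def test_monomorphic_segment_is_zero():
    z, f = _pipeline([[2, 0], [2, 2]])
    s = sg.segment_summary(z.slice_snps(0, 1), f.slice_snps(0, 1))
    np.testing.assert_array_equal(s.numerator, np.zeros((2, 2)))
    assert s.denominator == 0.0


def test_singleton_segments_sum_to_full_numerator(toy_genotypes):
    f = sg.allele_frequencies(toy_genotypes)
    z = sg.center(toy_genotypes, f)
    parts = list(sg.iter_segment_summaries(z, f, sg.plan_segments(2, 2)))
    total = parts[0].numerator + parts[1].numerator
    np.testing.assert_allclose(total, z.z @ z.z.T, atol=1e-15)


# ---------------------------------------------------------------------------
# ICGRM1 serialization


def _example_summary(rng, weighted=False, freq_source="observed"):
    x = random_dosages(rng, 4, 6)
    z, f = _pipeline(x)
    z.freq_source = freq_source
    w = sg.SnpWeights(z.snp_ids, rng.uniform(0, 2, 6)) if weighted else None
    return sg.segment_summary(z, f, w, segment_range=(10, 16))


@pytest.mark.parametrize("weighted", [False, True])
@pytest.mark.parametrize("freq_source", ["observed", "external"])
def test_summary_round_trip_bit_exact(tmp_path, rng, weighted, freq_source):
    s = _example_summary(rng, weighted, freq_source)
    path = tmp_path / "s.icgrm"
    sg.write_summary(s, path)
    back = sg.read_summary(path)
    assert back.individual_ids == s.individual_ids
    assert (back.start, back.end) == (s.start, s.end)
    assert back.snp_id_first == s.snp_id_first
    assert back.snp_id_last == s.snp_id_last
    assert back.weighted == s.weighted
    assert back.freq_source == s.freq_source
    assert back.denominator == s.denominator
    np.testing.assert_array_equal(back.numerator, s.numerator)
    assert peek_summary_range(path) == (10, 16)


def test_truncated_file_rejected(tmp_path, rng):
    path = tmp_path / "s.icgrm"
    sg.write_summary(_example_summary(rng), path)
    data = path.read_bytes()
    path.write_bytes(data[:-1])
    with pytest.raises(CorruptSummaryError):
        sg.read_summary(path)


def test_corrupted_payload_rejected(tmp_path, rng):
    path = tmp_path / "s.icgrm"
    sg.write_summary(_example_summary(rng), path)
    data = bytearray(path.read_bytes())
    data[len(data) // 2] ^= 0xFF
    path.write_bytes(bytes(data))
    with pytest.raises(CorruptSummaryError):
        sg.read_summary(path)


def test_version_bump_rejected_naming_both(tmp_path, rng):
    path = tmp_path / "s.icgrm"
    sg.write_summary(_example_summary(rng), path)
    data = bytearray(path.read_bytes())
    data[7] = 9  # version byte follows the 7-byte magic
    path.write_bytes(bytes(data))
    with pytest.raises(UnsupportedVersionError, match="version 9.*version 1"):
        sg.read_summary(path)


def test_bad_magic_rejected(tmp_path):
    path = tmp_path / "s.icgrm"
    path.write_bytes(b"NOTGRM1" + b"\x00" * 64)
    with pytest.raises(CorruptSummaryError, match="magic"):
        sg.read_summary(path)


# ---------------------------------------------------------------------------
# integration


def test_combine_toy_equals_one_pass(toy_genotypes):
    f = sg.allele_frequencies(toy_genotypes)
    z = sg.center(toy_genotypes, f)
    parts = list(sg.iter_segment_summaries(z, f, sg.plan_segments(2, 2)))
    combined = sg.combine_summaries(parts)
    np.testing.assert_allclose(combined.matrix, [[2.0, -2.0], [-2.0, 2.0]], atol=0)
    assert combined.n_snps_used == 2


def test_single_segment_is_identity_split(rng):
    x = random_dosages(rng, 6, 9)
    z, f = _pipeline(x)
    full = sg.grm_full(z, f)
    one = sg.combine_summaries(
        list(sg.iter_segment_summaries(z, f, sg.plan_segments(9, 1)))
    )
    assert np.abs(one.matrix - full.matrix).max() <= 1e-12
    assert one.denominator == pytest.approx(full.denominator, rel=1e-15)


@given(
    n=st.integers(2, 8),
    k=st.integers(7, 30),
    missing_rate=st.sampled_from([0.0, 0.1]),
    weighted=st.booleans(),
    seed=st.integers(0, 2**20),
)
@settings(max_examples=40, derandomize=True, deadline=None)
def test_split_combine_exactness(n, k, missing_rate, weighted, seed):
    """The central claim: for every part count, combining segment summaries
    reproduces the one-pass GRM within 1e-10 entrywise (weighted included)."""
    local = np.random.default_rng(seed)
    x = random_dosages(local, n, k, missing_rate)
    z, f = _pipeline(x)
    w = sg.SnpWeights(z.snp_ids, local.uniform(0, 2, k)) if weighted else None
    full = sg.grm_weighted(z, f, w) if weighted else sg.grm_full(z, f)
    for d in (1, 2, 3, 5, 7, k):
        parts = list(sg.iter_segment_summaries(z, f, sg.plan_segments(k, d), w))
        combined = sg.combine_summaries(parts)
        assert np.abs(combined.matrix - full.matrix).max() <= 1e-10
        assert combined.n_snps_used == k


def test_combine_order_invariance(rng):
    x = random_dosages(rng, 5, 12)
    z, f = _pipeline(x)
    parts = list(sg.iter_segment_summaries(z, f, sg.plan_segments(12, 4)))
    ref = sg.combine_summaries(parts)
    for perm in ([3, 1, 0, 2], [2, 3, 1, 0]):
        got = sg.combine_summaries([parts[i] for i in perm])
        np.testing.assert_array_equal(got.matrix, ref.matrix)  # bit-identical


def test_denominator_additivity(rng):
    x = random_dosages(rng, 4, 20)
    z, f = _pipeline(x)
    whole = float(np.sum(f.p * (1.0 - f.p)))
    parts = list(sg.iter_segment_summaries(z, f, sg.plan_segments(20, 7)))
    total = sum(s.denominator for s in parts)
    assert total == pytest.approx(whole, rel=1e-12)


def test_combine_rejects_mismatched_individual_order(rng):
    x = random_dosages(rng, 3, 4)
    z, f = _pipeline(x)
    a = sg.segment_summary(z.slice_snps(0, 2), f.slice_snps(0, 2), segment_range=(0, 2))
    b = sg.segment_summary(z.slice_snps(2, 4), f.slice_snps(2, 4), segment_range=(2, 4))
    b.individual_ids = [b.individual_ids[1], b.individual_ids[0], b.individual_ids[2]]
    with pytest.raises(IncompatibleSummariesError, match="position 0"):
        sg.combine_summaries([a, b])


def test_combine_rejects_mixed_modes(rng):
    x = random_dosages(rng, 3, 4)
    z, f = _pipeline(x)
    w = sg.SnpWeights(z.snp_ids, np.ones(4))
    plain = sg.segment_summary(z.slice_snps(0, 2), f.slice_snps(0, 2), segment_range=(0, 2))
    weighted = sg.segment_summary(
        z.slice_snps(2, 4), f.slice_snps(2, 4), w.slice_snps(2, 4), segment_range=(2, 4)
    )
    with pytest.raises(IncompatibleSummariesError, match="weighted"):
        sg.combine_summaries([plain, weighted])

    other = sg.segment_summary(z.slice_snps(2, 4), f.slice_snps(2, 4), segment_range=(2, 4))
    other.freq_source = "external"
    with pytest.raises(IncompatibleSummariesError, match="frequency"):
        sg.combine_summaries([plain, other])


def test_combine_rejects_overlap_and_warns_on_gap(rng):
    x = random_dosages(rng, 3, 6)
    z, f = _pipeline(x)
    parts = list(sg.iter_segment_summaries(z, f, sg.plan_segments(6, 3)))
    with pytest.raises(IncompatibleSummariesError, match="overlap"):
        sg.combine_summaries([parts[0], parts[0], parts[1]])
    with pytest.warns(CoverageGapWarning):
        subset = sg.combine_summaries([parts[0], parts[2]])
    assert subset.n_snps_used == 4


def test_combine_denominator_zero():
    z, f = _pipeline([[2, 2], [2, 2]])
    s = sg.segment_summary(z, f)
    with pytest.raises(DenominatorZeroError):
        sg.combine_summaries([s])


def test_streaming_combine_matches_in_memory(tmp_path, rng):
    x = random_dosages(rng, 5, 14)
    z, f = _pipeline(x)
    parts = list(sg.iter_segment_summaries(z, f, sg.plan_segments(14, 5)))
    paths = []
    for i, s in enumerate(parts):
        p = tmp_path / f"part{i}.icgrm"
        sg.write_summary(s, p)
        paths.append(p)
    streamed = sg.combine_summary_files(list(reversed(paths)))
    in_memory = sg.combine_summaries(parts)
    np.testing.assert_array_equal(streamed.matrix, in_memory.matrix)
    assert streamed.individual_ids == in_memory.individual_ids
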