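# Methods

## Estimator

For n diploid individuals genotyped at K biallelic SNPs, let `x_mj ∈
{0,1,2}` be the dosage of the counted allele and `p_j` its frequency.  With
`z_mj = x_mj − 2 p_j` (matrix Z), the genomic relationship matrix is

    G = Z Z' / (2 Σ_j p_j (1 − p_j)).

The pairwise entry `G_mn = Σ_j z_mj z_nj / (2 Σ_j p_j(1 − p_j))` scales the
shared-allele covariance by the expected heterozygosity so that, under
Hardy–Weinberg equilibrium and unrelatedness, diagonal entries have
expectation near 1.  The SNP-weighted variant replaces the numerator by
`Z D Z'` with `D = diag(d_j)`, `d_j ≥ 0`.  **The denominator stays
unweighted in the weighted variant.**  Some of the literature normalizes by
`Σ d_j p_j(1−p_j)` instead; we keep the unweighted form deliberately, which
makes the estimator homogeneous in the weights (scaling all `d_j` by c
scales G by c).  Users who want the other normalization can rescale the
weights to mean 1.

## Additive decomposition

Numerator and denominator are both plain sums over SNPs, so for any
partition of the K SNPs into disjoint segments s = 1..d,

    D_s = Z_s Z_s'           (n × n),
    N_s = Σ_{j∈s} p_j(1−p_j) (scalar),
    G   = (Σ_s D_s) / (2 Σ_s N_s).

This regroups the same floating-point sums; it is algebraically exact, and
empirically the regrouping noise is at the 1e-15 level (the acceptance
checks bound it at 1e-10).  Segments are contiguous index ranges over the
input SNP order — the estimator is indifferent to how SNPs are grouped, so
chromosome-aware planning is unnecessary (per-chromosome GRMs fall out of
passing explicit ranges).  Segment boundaries are 0-based half-open in all
file metadata; logs print 1-based inclusive for humans.

Crucial consistency requirement: every segment must be centered with the
*same* `p_j` source.  Observed frequencies are computed per SNP from the
full cohort (so per-segment computation sees the identical values), or an
external frequency file is supplied — e.g. when cohorts are processed
separately.  Summaries record their frequency source and the combine step
refuses to mix sources, as it refuses to mix weighted with unweighted
summaries or summaries whose individual lists differ in content or order.

Overlapping segments are a hard error (SNPs would be double-counted —
always wrong); gaps only raise a `CoverageGapWarning`, because combining a
subset of segments legitimately yields the GRM of that genome subset.

## Parameters and conventions

- **Allele frequency estimator** (default): observed sample frequency,
  `p_j = Σ_m x_mj / (2 n_j)` over the `n_j` non-missing genotypes — the
  field-standard choice for this estimator.  External frequencies override.
- **Missing genotypes**: mean-imputed, i.e. `z = 0` after centering.  This
  keeps numerator and denominator defined without dropping individuals, and
  (because observed `p_j` is computed over the same non-missing set) leaves
  column sums of Z exactly zero.
- **Allele orientation**: dosages count the VCF ALT allele; TSV/PLINK-raw
  codings are taken as-is.  G is invariant to flipping any SNP's orientation
  (z_mj and z_nj flip sign together), so this is a convention, not a
  correctness issue.
- **Monomorphic SNPs** are retained: they contribute zero to both sums, and
  keeping them makes SNP counts match the input.  If *all* SNPs are
  monomorphic the denominator is zero and construction fails loudly.
- **Multiallelic VCF records** are skipped with a counted warning — the
  model is biallelic; splitting them is QC-tool territory.
- **Precision**: all accumulation and all summary payloads are 64-bit
  floats; only the GCTA binary output dialect downcasts to 32-bit, matching
  that format's convention.
- **Threads**: the `--threads_num` flag caps the BLAS pool.  Accumulation
  order per segment is fixed, so parallelism changes wall time only; summary
  files are byte-identical at any thread count.

## Numerical choices

- The n × n cross-product uses a BLAS symmetric rank-k update (`dsyrk`) on
  the lower triangle, mirrored exactly on materialization, so G is
  symmetric by construction (`G == G.T` bitwise).
- The weighted numerator is computed as `(Z√D)(Z√D)'`, valid since all
  weights are nonnegative; with unit weights this is bit-identical to the
  unweighted path.
- Summaries are integrated in order of segment start regardless of the
  order supplied, making the combined GRM bit-identical under permutation
  of inputs.  The streaming combiner (`combine_summary_files`) reads one
  file at a time after a fixed-offset header peek, so integration memory is
  one accumulator plus one summary.
- The ICGRM1 container carries magic bytes, format version, mode flags,
  dimensions, the segment range and its terminal SNP IDs, the individual
  IDs, N_s, the lower-triangle numerator (row-major, 64-bit LE), and a
  trailing CRC-32 of the payload.  Truncation, bit-flips and version bumps
  are all rejected before any object is returned.

## Synthetic data

The simulators generate the study conditions for every test; no external
dataset exists.

- `simulate_unrelated`: per SNP, `p ~ Uniform(maf_low, maf_high)` (defaults
  0.05–0.5, a typical post-QC array spectrum); genotypes `Binomial(2, p)`
  i.i.d. (HWE).  Under observed-frequency centering, column sums of Z are
  zero, so row sums of G vanish, mean diagonal → 1 and mean off-diagonal →
  −1/(n−1) as K grows.
- `simulate_pedigree`: founders as above; each child receives one allele
  per locus from each parent (`Bernoulli(g/2)` — exact gamete dropping for
  exchangeable alleles).  This supplies known expected kinship: exactly 0.5
  realized for parent–offspring, 0 for founders.

What the simulators do **not** emulate: linkage disequilibrium (the
estimator is a per-SNP sum, so LD adds no test power), genotyping error,
allele-frequency spectra skewed toward rare variants, population structure
or selection.  Passing tests therefore certify the *algebra and the
pipeline* — exact split/combine equivalence, kinship recovery at HWE — not
robustness of GRM-based inference to those real-data features, which is a
property of the estimator itself, not of this implementation.

## Problem sizes used in the checks

Exactness is verified at n = 500, K = 10,000 for part counts 1–200;
kinship recovery at K = 50,000 with 30 founder pairs; oracle agreement on
100 micro-instances (n ≤ 10, K ≤ 20) against a plain double-loop
evaluation; the memory comparison at n = 2,000, K = 100,000 with d = 50,
measured as subprocess peak RSS.  These sizes exercise every code path —
BLAS blocking, serialization, streaming integration — while the exactness
of the decomposition itself is size-independent.  On that memory benchmark
the segmented path peaks below one third of the one-pass peak; the gap
widens with K since the segment step's footprint does not grow with it.

## Limitations

- No PLINK `.bed` binary parsing (planned extension); no imputation beyond
  mean; no QC filtering beyond monomorphic handling.
- No estimation of SNP weights — they are consumed, not produced.
- No alternative GRM estimators (per-SNP standardization, dominance GRM).
- No distributed scheduler: the decomposition is exposed so any scheduler
  can drive it.
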