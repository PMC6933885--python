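"""Peak-memory measurement of the one-pass vs the segment-wise GRM path.

The point of the segment-wise decomposition is that the segment step touches
only one n x n accumulator plus a single segment of genotypes, so its peak
resident memory is bounded independently of the genome-wide SNP count.  This
module makes that claim measurable: ``python -m seggrm.bench`` runs either
path in a fresh interpreter on simulated data and prints its own peak RSS
(``ru_maxrss``) as JSON, and :func:`measure_peak_rss` drives such a worker
as a subprocess so the parent's allocations never contaminate the reading.

The chunked mode exercises the real out-of-core path: each segment's
summary is written to disk in the ICGRM1 container and the files are then
streamed back through :func:`seggrm.chunking.combine_summary_files`.
"""

from __future__ import annotations

import argparse
import json
import os
import resource
import subprocess
import sys
import tempfile
from pathlib import Path

__all__ = ["run_worker", "measure_peak_rss"]


def run_worker(mode: str, n: int, n_snps: int, parts: int, seed: int) -> dict:
    """Simulate genotypes and build the GRM via the requested path.

    Returns summary figures (trace, one off-diagonal entry, peak RSS in KiB)
    used both for the memory comparison and as a cross-path correctness
    fingerprint.
    """
    import numpy as np

    from .chunking import combine_summary_files, plan_segments, segment_summary, write_summary
    from .genotype_io import allele_frequencies, center
    from .grm_core import grm_full
    from .simulate import SimConfig, simulate_unrelated

    g = simulate_unrelated(SimConfig(n_individuals=n, n_snps=n_snps, seed=seed))
    freqs = allele_frequencies(g)
    if mode == "full":
        grm = grm_full(center(g, freqs), freqs)
    elif mode == "chunked":
        plan = plan_segments(g.n_snps, parts)
        with tempfile.TemporaryDirectory(prefix="seggrm-bench-") as tmp:
            paths = []
            for s, (a, b) in enumerate(plan.boundaries):
                # center only this segment: full Z is never materialized
                z_seg = center(g.slice_snps(a, b), freqs.slice_snps(a, b))
                summary = segment_summary(
                    z_seg, freqs.slice_snps(a, b), segment_range=(a, b)
                )
                path = Path(tmp) / f"part{s:04d}.icgrm"
                write_summary(summary, path)
                paths.append(path)
                del z_seg, summary
            grm = combine_summary_files(paths)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    peak_kib = resource.getrusage(resource.RUSAGE_SELF).ru_maxrss
    return {
        "mode": mode,
        "n": n,
        "n_snps": n_snps,
        "parts": parts,
        "trace": float(np.trace(grm.matrix)),
        "g01": float(grm.matrix[0, 1]),
        "denominator": float(grm.denominator),
        "peak_rss_kib": int(peak_kib),
    }


def measure_peak_rss(mode: str, n: int, n_snps: int, parts: int, seed: int) -> dict:
    """Run the worker in a fresh single-threaded interpreter; parse its JSON."""
    env = dict(os.environ)
    for var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
        env[var] = "1"
    cmd = [
        sys.executable,
        "-m",
        "seggrm.bench",
        "--mode",
        mode,
        "--n-individuals",
        str(n),
        "--n-snps",
        str(n_snps),
        "--parts",
        str(parts),
        "--seed",
        str(seed),
    ]
    out = subprocess.run(cmd, env=env, capture_output=True, text=True, check=True)
    return json.loads(out.stdout)


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="python -m seggrm.bench",
        description="measure peak RSS of one GRM-construction path",
    )
    parser.add_argument("--mode", choices=("full", "chunked"), required=True)
    parser.add_argument("--n-individuals", type=int, required=True)
    parser.add_argument("--n-snps", type=int, required=True)
    parser.add_argument("--parts", type=int, default=1)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args(argv)
    result = run_worker(args.mode, args.n_individuals, args.n_snps, args.parts, args.seed)
    json.dump(result, sys.stdout)
    sys.stdout.write("\n")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
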