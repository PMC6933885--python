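#!/usr/bin/env bash
# The two-step shell workflow: per-segment summary statistics, then
# integration into a GRM in GCTA text format.  Each `seggrm grm` call is
# independent — run them on different machines, collect the .icgrm files,
# and combine anywhere.
set -euo pipefail
cd "$(mktemp -d)"

seggrm simulate --n_individuals 50 --n_snps 2000 --seed 11 --out_file geno.tsv

seggrm grm --in_file geno.tsv --part 1/4 --out_file part1.icgrm
seggrm grm --in_file geno.tsv --part 2/4 --out_file part2.icgrm
seggrm grm --in_file geno.tsv --part 3/4 --out_file part3.icgrm
seggrm grm --in_file geno.tsv --part 4/4 --out_file part4.icgrm

printf '%s\n' part1.icgrm part2.icgrm part3.icgrm part4.icgrm > parts.txt
seggrm combine parts.txt --out_file cohort --dialect gcta_gz

echo "--- first lines of the combined GRM ---"
zcat cohort.grm.gz | head -3
head -3 cohort.grm.id
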