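"""Validate the estimator against known pedigree kinship.

Gamete dropping gives ground truth the estimator must recover: a child
shares exactly half its genome with each parent (expected relationship 0.5)
and founders are mutually unrelated (expected 0).  A reasonably sized cohort
matters: allele frequencies are estimated from the sample, which shifts
every off-diagonal by about -1/(n-1) — negligible at n = 60, overwhelming
at n = 4.
"""

import numpy as np

import seggrm as sg

n_families = 20  # founder pairs 2f, 2f+1 -> child 40+f
pedigree = [(2 * n_families + f, 2 * f, 2 * f + 1) for f in range(n_families)]
cfg = sg.SimConfig(
    n_individuals=3 * n_families, n_snps=50_000, seed=7, pedigree=pedigree
)
g = sg.simulate_pedigree(cfg)
freqs = sg.allele_frequencies(g)
grm = sg.grm_full(sg.center(g, freqs), freqs)

po = [grm.matrix[c, p] for c, p1, p2 in pedigree for p in (p1, p2)]
founders = range(2 * n_families)
unrel = [grm.matrix[a, b] for i, a in enumerate(founders)
         for b in list(founders)[i + 1:]]
print(f"parent-offspring mean G = {np.mean(po):.3f}  expect ~0.5")
print(f"unrelated-founder mean G = {np.mean(unrel):.3f}  expect ~0")
print(f"diagonal mean            = {np.diag(grm.matrix).mean():.3f}  expect ~1")
# Parent-offspring pairs cluster tightly around 0.5 because a child shares
# exactly one allele per locus with each parent — the only noise is the
# finite SNP count and the frequency-estimation shift.
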