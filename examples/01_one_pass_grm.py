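"""Build a VanRaden GRM in one pass, plain and SNP-weighted.

A tiny two-individual, two-SNP dosage matrix makes every number checkable by
hand: observed frequencies are 0.5 at both SNPs, so the centered matrix is
Z = [[-1, 1], [1, -1]] and the denominator 2*(0.25 + 0.25) = 1.
"""

import numpy as np

import seggrm as sg

g = sg.GenotypeMatrix(
    individual_ids=["ind1", "ind2"],
    snp_ids=["s1", "s2"],
    dosages=np.array([[0, 2], [2, 0]]),
)
freqs = sg.allele_frequencies(g)
z = sg.center(g, freqs)

grm = sg.grm_full(z, freqs)
print("allele frequencies:", freqs.p)
print("denominator 2*sum p(1-p):", grm.denominator)
print("G =")
print(grm.matrix)
# Diagonal 2: each individual is homozygous at both (maximally informative)
# SNPs; off-diagonal -2: the two individuals carry opposite alleles.

weights = sg.SnpWeights(["s1", "s2"], np.array([1.0, 3.0]))
grm_w = sg.grm_weighted(z, freqs, weights)
print("weighted G (d = [1, 3]) =")
print(grm_w.matrix)
# Tripling SNP 2's weight triples its contribution to the numerator while
# the denominator stays unweighted, so every entry doubles from 2 to 4.
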