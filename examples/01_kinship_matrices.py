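"""Relationship matrices from a pedigree.

Builds one three-generation family of 16 and prints the kinship and
dominance (Δ7) coefficients for a few textbook relationships.  φ is the
probability that a random allele from each of two individuals is
identical by descent; Δ7 is the probability that both allele pairs are
IBD, which drives dominance covariance.
"""

from pedscore import delta7_matrix, kinship_matrix
from pedscore.simkit import three_generation_pedigree

ped = three_generation_pedigree("fam1")
phi = kinship_matrix(ped)
d7 = delta7_matrix(ped)
ids = phi.ids

pairs = [
    ("parent-offspring", "fam1_gf", "fam1_c1"),
    ("full siblings", "fam1_c1k1", "fam1_c1k2"),
    ("first cousins", "fam1_c1k1", "fam1_c2k1"),
    ("spouses", "fam1_c1", "fam1_s1"),
]
print(f"pedigree: {ped.n} individuals, {len(ped.founders)} founders")
print(f"{'pair':20s} {'phi':>8s} {'delta7':>8s}")
for name, a, b in pairs:
    i, j = ids.index(a), ids.index(b)
    print(f"{name:20s} {phi.values[i, j]:8.4f} {d7.values[i, j]:8.4f}")
# Expected: phi = 0.25, 0.25, 0.0625, 0; delta7 = 0, 0.25, 0, 0.
# The additive kernel used by the covariance model is 2*phi.
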