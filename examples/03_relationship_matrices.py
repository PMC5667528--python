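"""Relationship matrices: pedigree A, molecular coancestry, VanRaden G,
the combined pedigree-genomic Gamma, and the cross-level dominance Gamma_D.

The combined matrix lets ungenotyped relatives enter a genomic evaluation:
its inverse is (0.5A)^-1 plus a genotyped-block correction G^-1 - (0.5A22)^-1.
"""

import numpy as np

from hybridgs import (PopulationSpec, coancestry_summary,
                      combined_gamma_inverse, dominance_gamma,
                      molecular_coancestry, pedigree_relationship,
                      simulate_breeding_population, simulate_mating_design,
                      naive_impute, vanraden_G)

spec = PopulationSpec("A", n_founders=4, n_generations=2,
                      n_individuals_per_generation=18, n_snps=400, seed=11)
ped, gt = simulate_breeding_population(spec)

A = pedigree_relationship(ped)
print(f"pedigree A over {len(A.ids)} individuals: "
      f"mean inbreeding {np.diag(A.values).mean() - 1:.3f}")

S = molecular_coancestry(gt)
print(f"molecular similarity: mean off-diagonal "
      f"{S.values[np.triu_indices_from(S.values, 1)].mean():.3f}")

# G needs complete polymorphic dosages: impute, then drop constant columns
imp = naive_impute(gt, ped)
poly = imp.dosage.std(axis=0) > 0
imp = imp.subset(snp_ids=list(imp.snps.loc[poly, "snp_id"]))
G = vanraden_G(imp)
print(f"VanRaden G from {imp.n_snps} SNPs: mean diagonal "
      f"{np.diag(G.values).mean():.2f}")

# pretend the first third of individuals were never genotyped
genotyped = gt.ids[len(gt.ids) // 3:]
sub = imp.subset(genotyped)
poly = sub.dosage.std(axis=0) > 0  # subsetting can fix previously varying loci
G2 = vanraden_G(sub.subset(snp_ids=list(sub.snps.loc[poly, "snp_id"])))
comb = combined_gamma_inverse(A, G2, genotyped)
print(f"combined Gamma orders {len(comb.gamma.ids)} individuals "
      f"({len(comb.genotyped_ids)} genotyped); blend weight "
      f"{comb.blend_weight}")

# validation-training relatedness summary (f_max V-T)
val, train = gt.ids[-5:], gt.ids[:-5]
s = coancestry_summary(A, val, train)
print(f"mean maximum coancestry of validation with training: {s.mean:.2f} "
      f"(range {s.min:.2f}-{s.max:.2f}); 0.25 marks a full sib or parent")
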