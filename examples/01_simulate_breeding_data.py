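"""Simulate a two-group hybrid breeding dataset.

Builds two parental populations (a few founders, selfing, mating among
relatives), an incomplete-factorial mating design between them, GBS-like
genotypes, and hybrid phenotypes under the GCA/SCA variance structure.
"""

import numpy as np

from hybridgs import (PopulationSpec, simulate_breeding_population,
                      simulate_mating_design, simulate_phenotypes)
from hybridgs.pipeline import merge_tables
from hybridgs.simulate import SimVarianceComponents, TrialLayout

spec_a = PopulationSpec("A", n_founders=4, n_generations=2,
                        n_individuals_per_generation=20, n_snps=500, seed=1)
spec_b = PopulationSpec("B", n_founders=4, n_generations=2,
                        n_individuals_per_generation=20, n_snps=500, seed=2)
ped_a, gt_a = simulate_breeding_population(spec_a)
ped_b, gt_b = simulate_breeding_population(spec_b)
genotypes = merge_tables(gt_a, gt_b)

design = simulate_mating_design(ped_a.group_ids("A")[-12:],
                                ped_b.group_ids("B")[-12:],
                                crosses_per_parent=4, seed=3)
phen, truth = simulate_phenotypes(
    design, ped_a, ped_b, genotypes,
    SimVarianceComponents(mean=120.9, var_gca_a=25, var_gca_b=55, var_sca=3),
    TrialLayout(n_trials=2, n_blocks=5, palms_per_plot=3), seed=4)

miss = np.isnan(gt_a.dosage).mean()
print(f"{genotypes.n_individuals} individuals x {genotypes.n_snps} SNPs "
      f"(each group typed on its own panel); "
      f"{miss:.1%} missing calls in group A (GBS-like)")
print(f"{len(design.cross_ids)} hybrid crosses, {len(phen)} phenotype records")
print(f"true GCA variances: A {truth.gca_a.var(ddof=1):.1f}, "
      f"B {truth.gca_b.var(ddof=1):.1f} (generating values 25 / 55)")
# The phenotype table is ready for QC, relationship matrices and model fits.
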