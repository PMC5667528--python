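"""Genomic prediction of unobserved hybrid crosses.

Fits the GCA/SCA mixed model three ways: TBLUP with identity Gammas gives
design-adjusted reference cross values; GBLUP (marker Gammas) and PBLUP
(pedigree Gammas) predict validation crosses whose parents have no
phenotyped progeny.  Accuracy is the Pearson correlation with the
reference (here: the known simulated truth).
"""

import pandas as pd

from hybridgs import (PopulationSpec, accuracy, simulate_breeding_population,
                      simulate_mating_design, simulate_phenotypes,
                      split_validation)
from hybridgs.core import MatingDesign
from hybridgs.evaluate import build_genomic_gammas
from hybridgs.mixedmodel import (genomic_predict, pedigree_gammas,
                                 reference_values)
from hybridgs.pipeline import merge_tables
from hybridgs.simulate import SimVarianceComponents, TrialLayout

spec_a = PopulationSpec("A", n_founders=3, n_generations=2,
                        n_individuals_per_generation=40, n_snps=100, seed=61,
                        gbs_noise=False, mating_related_prob=0.6)
spec_b = PopulationSpec("B", n_founders=3, n_generations=2,
                        n_individuals_per_generation=40, n_snps=100, seed=62,
                        gbs_noise=False, mating_related_prob=0.6)
ped_a, gt_a = simulate_breeding_population(spec_a)
ped_b, gt_b = simulate_breeding_population(spec_b)
gt = merge_tables(gt_a, gt_b)
pa, pb = ped_a.group_ids("A")[-40:], ped_b.group_ids("B")[-40:]

md_train = simulate_mating_design(pa[:28], pb[:28], 5, seed=63)
md_val = simulate_mating_design(pa[28:], pb[28:], 4, seed=64)
design = MatingDesign(pd.concat([md_train.crosses, md_val.crosses],
                                ignore_index=True))
phen, truth = simulate_phenotypes(
    design, ped_a, ped_b, gt,
    SimVarianceComponents(var_gca_a=25, var_gca_b=55, var_sca=2),
    TrialLayout(n_trials=1, n_blocks=3, palms_per_plot=2, ages=(3, 4, 5)),
    seed=65)
train_phen = phen[~phen["cross"].isin(md_val.cross_ids)]

# reference cross values: identity Gammas, no shrinkage to family means
ref, _, _, fit = reference_values(train_phen, md_train, mode="cross_values")
print("REML variance components (training data):",
      {k: round(v, 1) for k, v in fit.vc.by_term.items()},
      "residual", round(fit.vc.residual, 1))

true_vals = truth.cross_values(design)[md_val.cross_ids]
for label, gammas in (
        ("GBLUP", build_genomic_gammas(gt, design, ped_a, ped_b)),
        ("PBLUP", pedigree_gammas(design, ped_a, ped_b))):
    pred, ga, gb, _ = genomic_predict(train_phen, design, gammas,
                                      with_sca=False, vc=fit.vc)
    acc = accuracy(true_vals, pred.values[md_val.cross_ids])
    print(f"{label}: accuracy {acc:.2f} on {len(md_val.cross_ids)} "
          "unphenotyped validation crosses")
# GBLUP uses realized marker relationships and can separate full sibs;
# PBLUP only distinguishes families, so its accuracy is typically lower.
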