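"""GBS SNP quality control: depth masking, site filters, Mendelian checks.

Calls under 5 reads are set missing; sites with >50% missing data, mean
depth >500, or >5% Mendelian inconsistencies within a parental group are
dropped.  The report records counts per filter stage.
"""

import numpy as np

from hybridgs import (FilterConfig, PopulationSpec, apply_site_filters,
                      marker_stats, mendelian_filter, naive_impute,
                      simulate_breeding_population, subsample_snps)

spec = PopulationSpec("A", n_founders=4, n_generations=2,
                      n_individuals_per_generation=25, n_snps=2000, seed=7,
                      genotyping_error_rate=0.002)
ped, gt = simulate_breeding_population(spec)

filtered, rep1 = apply_site_filters(gt, FilterConfig())
print(f"site filters: {rep1.input_sites} -> {rep1.retained_sites} sites "
      f"({rep1.masked_low_depth_calls} low-depth calls masked, "
      f"{rep1.dropped_missingness} sites >50% missing)")

clean, rep2 = mendelian_filter(filtered, ped)
print(f"Mendelian check: {rep2.masked_mendelian_calls} impossible calls "
      f"masked, {rep2.input_sites - rep2.retained_sites} sites dropped")

stats = marker_stats(clean).snp_stats
print(f"retained markers: mean MAF {stats['maf'].mean():.2f}, "
      f"mean missingness {stats['missingness'].mean():.1%}, "
      f"mean depth {stats['mean_depth'].mean():.0f}")

low_miss = subsample_snps(clean, 200, strategy="min_missing")
sub = clean.subset(snp_ids=low_miss)
print(f"200 lowest-missingness SNPs have "
      f"{float(np.isnan(sub.dosage).mean()):.2%} missing data")
imputed = naive_impute(clean, ped)
print(f"after imputation: 0 missing cells "
      f"({imputed.n_individuals} x {imputed.n_snps})")
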