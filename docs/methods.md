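# Methods

## The hybrid GCA/SCA mixed model

Phenotype records of individual hybrid palms (one record per palm × age for
bunch production traits, one per palm for quality ratios) are modelled as

Y = Xβ + Zb + Z_A g_A + Z_B g_B + Z_D s_AB + e,

following the classical variance partition for inter-population hybrids:
each cross value decomposes into the general combining abilities (GCAs) of
its A and B parents plus a cross-specific deviation (SCA), which in an
A × B population with unrelated groups is the dominance effect. Fixed
effects are the overall mean, trial, block (nested in trial) and — for
production traits, where records span ages 3–7 — age as a 5-level factor.
Random design effects are elementary plot (nested in block and trial),
individual (permanent effect across ages), incomplete block for lattice
trials, and an age × cross interaction with covariance I ⊗ Γ_D (age as the
outer factor, crosses as the inner one; the ordering is a convention of
this implementation). Genetic covariances are σ²₍gA₎Γ_A, σ²₍gB₎Γ_B and
σ²_d Γ_D, with Γ_D(ab, a′b′) = Γ_A(a,a′)·Γ_B(b,b′) — the coefficient of
fraternity between crosses — materialised only over the observed crosses,
never as the full Kronecker product.

Treating age as a factor rather than a covariate is an assumption: the age
profile of bunch production is strongly non-linear over ages 3–7, so a
factor costs four degrees of freedom but avoids a functional-form choice.

### Model variants

* **TBLUP, cross values**: Γ_A = Γ_B = I. Parents are deliberately treated
  as unrelated so GCAs are not shrunk towards family means; the three-term
  sum ĝ_A(a) + ĝ_B(b) + ŝ_AB(ab) is then a design-adjusted cross value,
  used as the *reference* that other methods try to predict.
* **TBLUP, reference GCAs / PBLUP**: Γ = 0.5A per group, A the numerator
  relationship matrix (elements 2f_xy) from the tabular method. PBLUP is
  the control for genomic prediction: it models training–validation
  covariances through the pedigree only, so unphenotyped full sibs receive
  identical GCAs (a tested property) and within-family differences are
  invisible to it.
* **GBLUP**: per parental group, the marker matrix G (VanRaden: centred
  dosage cross-products over 2Σp(1−p), allele frequencies observed within
  the group) is combined with the pedigree via
  Γ⁻¹ = (0.5A)⁻¹ + [0 0; 0 G*⁻¹ − (0.5A₂₂)⁻¹], the single-step
  construction, so progeny-tested but ungenotyped parents stay in the
  analysis. G* = wG + (1−w)·0.5A₂₂ with default w = 0.99 guarantees
  invertibility; w is configurable and w = 1 allowed. The identity has two
  closed-form limits (no genotypes → 0.5A; all genotyped → G*) that the
  tests verify exactly, plus a dense conditional-expectation oracle for
  the mixed case.

Predicted cross values are reported with or without the ŝ term; reference
values always include it. Solutions are reported as returned by the mixed
model equations (fixed mean absorbed by β̂), with no post-hoc recentering.

### Solving and REML

Solutions come from Henderson's mixed-model equations, solved densely by
Cholesky factorisation; every returned fit carries its relative residual
norm (tests require ≤ 1e−8). Prediction error variances (PEVs) are read
off the inverse coefficient matrix and convert to individual selection
accuracies as √(1 − PEV/(Γ_ii σ²)).

Variance components are REML estimates. Two iterations are provided: EM
(monotone in the restricted likelihood, slow near boundaries) and
average-information (AI) updates with an automatic EM fallback whenever an
AI proposal leaves the parameter space; AI is the default. Both work on
the dense projection matrix P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹, appropriate for
the problem sizes of simulation studies (thousands of records), not for
national-evaluation scale. Convergence is declared when all components
change by < 1e−6 relatively or the restricted log-likelihood is stationary
to 1e−9 (components drifting to the zero boundary otherwise never settle in
relative terms); iterates are floored at 1e−10 × the phenotypic variance,
so boundary solutions surface as that floor. Over-parameterised fixed
effects are handled by reference-level constraints (first level dropped,
per nesting group for nested factors).

The estimand is REML itself; the specific algorithm is not — estimates are
validated against the closed-form balanced one-way ANOVA solution, EM/AI
cross-agreement, and a 50-replicate parameter-recovery experiment that
requires each mean estimate within two Monte-Carlo standard errors of its
generating value.

### Supporting statistics

The proportion of dominance variance uses the trace-normalised ratio
(Tr(Γ_D)/n_D)σ²_d / ((Tr(Γ_D)/n_D)σ²_d + (Tr(Γ_A)/n_A)σ²₍gA₎ +
(Tr(Γ_B)/n_B)σ²₍gB₎). Molecular coancestry is the allele-sharing
similarity index (mean of the four allele-identity indicators per locus,
averaged over shared called loci): the literature offers several closely
related estimators and no single canonical formula, so the simplest
similarity variant was chosen and is pinned by enumeration tests; pairs
with no shared called locus are flagged missing rather than guessed.

## SNP quality control

The filter chain runs in a fixed order — per-call depth mask (< 5 reads →
missing), biallelic-SNV requirement, site missingness (> 50% dropped),
mean-depth outliers (> 500, suspected duplicated regions), unmapped
contigs, then Mendelian checks — and reports counts per stage so order
effects stay visible. All thresholds are strict at equality ("more than"),
and all are configurable. Mendelian impossibility for biallelic dosages:
an offspring call is masked iff it requires an allele neither parent can
transmit (trios bound the offspring's alternate-allele count between
(s=2)+(d=2) and 2−(s=0)−(d=0); duos use the single known parent; unknown
or uncalled parents skip the check). Sites monomorphic within a parental
group, or with more than 5% inconsistent calls in that group, are dropped
from that group's panel; each group is filtered on its own marker panel
throughout.

Subsampling supports the two density-experiment strategies: uniform random
without replacement (seeded) and lowest-missingness, which is
deterministic with ties broken by higher MAF then genome order. The naive
imputer (rounded Mendelian expectation when both parents are called, else
rounded within-group mean) is a deliberately simple deterministic stand-in
so the pipeline is self-contained; the intended production path is the
VCF export/re-ingest interface to a dedicated phasing/imputation tool,
which can exploit pedigree haplotypes the naive rule cannot.

## The synthetic-data generator

The generator emulates the features of real hybrid-breeding data that the
analysis is sensitive to:

* **Population history** — each group descends from a handful of founders
  (default 4) through a few generations with selfing (default probability
  0.2) and preferential mating among relatives (0.3), producing the high
  inbreeding and family structure typical of closed breeding populations.
* **Markers** — unlinked biallelic loci; founder allele frequencies from a
  Beta(1.2, 4) distribution so the MAF histogram is right-skewed; per-call
  depth from a per-SNP lognormal-mean mixed Poisson centred near 70 reads;
  per-SNP missingness from a Beta(0.6, 4) (mean ≈ 0.13, right-skewed) —
  all in the range of reported GBS marker summaries for such populations.
  Genotyping errors can be injected to exercise the Mendelian filters.
* **Phenotypes** — true GCAs are sums of per-group additive SNP effects
  rescaled to the requested variance, so markers genuinely carry the
  signal genomic prediction is supposed to capture; SCAs are multivariate
  normal with the pedigree-implied Γ_D; trial / block / age-profile fixed
  effects and plot / individual / age × cross / residual deviations are
  added at their specified variances. Default variance components (GCA
  25 / 55 kg², SCA 5, plot 10, individual 30, age × cross 5, residual 80
  around a 120.9 kg mean) give heritabilities and an A-vs-B variance
  asymmetry in the range reported for FFB-like production traits.

What the generator does *not* emulate: linkage and LD decay (loci are
independent — none of the implemented analyses uses positional
information beyond ordering), selection during pedigree generation,
genotype-by-environment interaction, and sequence-level read error
processes. Passing tests therefore certify the statistical machinery —
estimability, unbiasedness, the GBLUP/PBLUP contrast under within-family
marker signal — not accuracy magnitudes on any real population, which
depend on LD structure and training-set composition the generator does not
model.

## The preselection-gain simulation

Per parental group, candidates' (g′, ĝ′_PT, ĝ′_GS) triples are trivariate
normal. The covariance is assembled from three scalars per group:
σ²_g′ (21.6 kg² in Group A, 56.4 in Group B), r_PT = r(ĝ′_PT, g′) (0.54 /
0.76) and r_GS,PT = r(ĝ′_GS, ĝ′_PT) (0.30 / 0.77). Var(ĝ′_PT) = σ²_g′·r_PT²
by the accuracy-inversion identity, and the genomic accuracy derives as
r_GS = r_GS,PT / r_PT. Group B's ratio is 0.77/0.76 ≈ 1.013 > 1 — an
artefact of rounded inputs — and is capped at 0.999 (configurable); with
the cap the correlation matrix is already positive definite, and a
nearest-PSD repair (eigenvalue clipping with unit diagonal restored)
stands by for parameterisations where it is not. The genomic GCA gets unit
variance: both selection stages are threshold-free top-k rankings, so its
scale cannot affect any outcome (a tested invariance). The cap is the one
reconstruction choice with any leverage on the preselected-scheme mean;
sensitivity over caps {0.95, 0.99, 0.999} moves the headline gain by well
under the Monte-Carlo error.

Each replicate draws fresh candidate populations. Conventional RRS progeny
tests a random 125 per group (the first 125 of an i.i.d. sample);
preselection instead progeny-tests the top 125 on ĝ′_GS out of the full
candidate pool. Both schemes then keep the top 10 per group on ĝ′_PT, and
the 100 selected hybrids average μ_FFB + ḡ′_A + ḡ′_B with true GCAs
centred at their theoretical mean of zero (sample-mean centring is
available as an option) and no SCA term. Both schemes are evaluated on the
same draws, which pairs the comparison and shrinks the Monte-Carlo error
of the gain. Ties in top-k selection are broken by draw order, a
measure-zero event for continuous values. Default 20,000 replicates; the
acceptance script runs all grid cells at that size in about a minute, and
2,000 replicates already put the Monte-Carlo standard error near 0.1 kg.

The economic chain is deterministic: extra kg/palm/yr × planting density
(143 palms/ha) × standing fraction (0.95) → t FFB/ha/yr; × mill oil
extraction rate (0.28) → kg oil/ha/yr; × price (640 US$/t) → US$/ha/yr.

## Evaluation protocol

Validation crosses are split into k = 6 near-equal random sets by default;
cross-value accuracy is the Pearson correlation between reference and
predicted values within each set, GCA accuracy a single correlation per
parental group (validation groups are small, so no replication). Density
sweeps re-draw SNP subsets — 26 random replicates, or 3 for the
deterministic lowest-missingness strategy — with the same count in both
parental groups and the same replicate seeds reusable across traits, then
rebuild G, refit and record accuracies. By default the sweep re-uses the
variance components of the full-marker fit instead of re-running REML per
subset; components are a property of the phenotypic model, not of the
marker panel, and re-estimation per subset is available by passing
`vc=None`. Method comparisons use a paired t-test over validation sets or
a fixed-effects ANOVA with prediction method, validation set and SNP
replicate as factors and no interactions (the factors are specified; the
error model is this package's assumption, checked for nominal type-I
error on simulated nulls). Summary statistics of adjusted cross values use
CV = SD/mean and the adjusted Fisher–Pearson sample skewness.

## Problem sizes and numerical choices

The test suite exercises the mixed model at a few hundred to ~2,000
records (tens of parents per group, 20–120 crosses) — large enough for
stable REML yet fast enough that the full suite runs in about a minute.
The acceptance script's only stochastic computation is the preselection
simulation, run at the full 20,000 replicates. Matrix inversions go
through Cholesky with a relative jitter of 1e−8·trace/n only when a Γ is
numerically semidefinite; the MME itself is never regularised. Boundary
REML estimates are floored (above) before entering the MME, since a zero
variance would make the coefficient matrix singular — dropping the term is
the cleaner alternative and is what `build_design`'s ModelSpec toggles are
for.

## Known limitations

* Dense linear algebra throughout: no sparse Γ⁻¹ factorisation, so
  population sizes beyond a few thousand records are out of scope.
* The naive imputer ignores haplotypes; accuracy studies that hinge on
  imputation quality should use the external-tool interface.
* Single-trait models only; no genotype-by-environment covariances, no
  spatial field-trend corrections, no metafounders, and none of the
  G-matrix depth corrections or LD weightings that have been proposed for
  GBS data.
* The pipeline's per-stage artifacts are plain text for transparency, and
  its scale defaults favour smoke-test speed over realism; study-scale
  runs should set the simulate/fit sections explicitly.
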