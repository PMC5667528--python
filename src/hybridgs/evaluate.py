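"""Accuracy-estimation protocol for genomic prediction of hybrid crosses.

Validation crosses are split into k random sets of (near-)equal size;
prediction accuracy is the Pearson correlation between reference and
predicted cross values within each set (and a single correlation per
parental group for GCAs, the validation groups being small).  The marker
density experiment re-draws SNP subsets (random, or the lowest-missingness
subset), rebuilds the genomic matrices with the same SNP count in both
parental groups, re-runs the genomic prediction, and records accuracies;
methods are compared with a paired t-test over validation sets or a
fixed-effects ANOVA with prediction method, validation set and SNP
replicate as factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .core import GammaStructure, GenotypeTable, MatingDesign, Pedigree
from .mixedmodel import (ModelSpec, VarianceComponents, genomic_predict,
                         pedigree_gammas)
from .qc import naive_impute, subsample_snps
from .relmat import combined_gamma_inverse, dominance_gamma, pedigree_relationship, vanraden_G


@dataclass
class EvaluationPlan:
    n_validation_sets: int = 6
    snp_density_grid: tuple[int | None, ...] = (200, 350, 500, 1000, 1500,
                                                2000, 3000, None)  # None = all
    reps_random: int = 26
    reps_min_missing: int = 3
    seed: int = 0


def split_validation(crosses: list[str], k: int, seed: int = 0) -> list[list[str]]:
    """Disjoint near-equal random partition of the crosses into k sets."""
    if k < 2:
        raise ValueError("need at least two validation sets")
    if k > len(crosses):
        raise ValueError("more sets than crosses")
    rng = np.random.default_rng(seed)
    order = list(crosses)
    rng.shuffle(order)
    base, rem = divmod(len(order), k)
    sets, start = [], 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        sets.append(order[start:start + size])
        start += size
    return sets


def accuracy(reference: pd.Series, predicted: pd.Series) -> float:
    """Pearson correlation between reference and predicted values (by id)."""
    common = reference.index.intersection(predicted.index)
    if len(common) < 3:
        raise ValueError("need at least three paired values")
    a = reference[common].to_numpy(float)
    b = predicted[common].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the value vectors")
    return float(scipy.stats.pearsonr(a, b).statistic)


def build_genomic_gammas(genotypes: GenotypeTable, design: MatingDesign,
                         pedigree_a: Pedigree, pedigree_b: Pedigree,
                         snp_ids_a: list[str] | None = None,
                         snp_ids_b: list[str] | None = None,
                         blend_weight: float = 0.99) -> GammaStructure:
    """Combined pedigree-genomic Gammas for GBLUP, one per parental group.

    Each group's G is built from its own (optionally subsampled) markers on
    observed within-group frequencies, imputed with the naive imputer, and
    combined with the group pedigree through the inverse-combination
    formula so that ungenotyped parents are carried by the pedigree.
    """
    out = {}
    for label, ped, snp_ids in (("A", pedigree_a, snp_ids_a),
                                ("B", pedigree_b, snp_ids_b)):
        parents = (design.parents_a if label == "A" else design.parents_b)
        genotyped = [i for i in parents if i in set(genotypes.ids)]
        A = pedigree_relationship(ped, parents)
        if genotyped:
            sub = genotypes.subset(genotyped, snp_ids)
            sub = naive_impute(sub, ped)
            poly = (sub.dosage.std(axis=0) > 0)
            sub = sub.subset(snp_ids=list(sub.snps.loc[poly, "snp_id"]))
            G = vanraden_G(sub)
        else:
            G = None
        comb = combined_gamma_inverse(A, G, genotyped, blend_weight)
        out[label] = comb.gamma.reorder(parents)
    gd = dominance_gamma(out["A"], out["B"], design)
    return GammaStructure(out["A"], out["B"], gd)


def density_sweep(plan: EvaluationPlan, genotypes: GenotypeTable,
                  design: MatingDesign, pedigree_a: Pedigree,
                  pedigree_b: Pedigree, train_phenotypes: pd.DataFrame,
                  reference: pd.Series, validation_sets: list[list[str]],
                  vc: VarianceComponents | None = None,
                  spec: ModelSpec | None = None,
                  strategies: tuple[str, ...] = ("random",),
                  with_sca: bool = False,
                  trait: str = "trait") -> pd.DataFrame:
    """Accuracy per (density, strategy, SNP replicate, validation set).

    Marker subsets are drawn with the same count in both parental groups
    (within each group's own marker panel) and the identical replicate
    seeds are intended to be reused across traits.  Variance components may
    be supplied to reuse the full-marker REML estimates instead of
    re-estimating per subset.
    """
    group_tables = {}
    for label, parents in (("A", design.parents_a), ("B", design.parents_b)):
        genotyped = [i for i in parents if i in set(genotypes.ids)]
        group_tables[label] = genotypes.subset(genotyped)
    rows = []
    for density in plan.snp_density_grid:
        for strategy in strategies:
            if density is None:
                reps = 1
            elif strategy == "random":
                reps = plan.reps_random
            else:
                reps = plan.reps_min_missing
            for rep in range(reps):
                sub_ids = {}
                for label, tab in group_tables.items():
                    if density is None:
                        sub_ids[label] = None
                    else:
                        if density > tab.n_snps:
                            raise ValueError(
                                f"density {density} exceeds the {tab.n_snps} "
                                f"markers of group {label}")
                        sub_ids[label] = subsample_snps(
                            tab, density, strategy,
                            seed=plan.seed + 7919 * rep + (density or 0))
                gammas = build_genomic_gammas(
                    genotypes, design, pedigree_a, pedigree_b,
                    snp_ids_a=sub_ids["A"], snp_ids_b=sub_ids["B"])
                pred, _, _, _ = genomic_predict(
                    train_phenotypes, design, gammas, spec,
                    with_sca=with_sca, vc=vc)
                for s, members in enumerate(validation_sets):
                    rows.append({
                        "trait": trait, "method": "GBLUP",
                        "density": 0 if density is None else density,
                        "strategy": strategy, "replicate": rep, "set": s,
                        "accuracy": accuracy(reference[members],
                                             pred.values[members]),
                    })
    return pd.DataFrame(rows)


def aggregate_accuracy(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of accuracy per (trait, method, density, strategy)."""
    return (results.groupby(["trait", "method", "density", "strategy"])
            ["accuracy"].agg(["mean", "std", "count"]).reset_index())


@dataclass
class ComparisonResult:
    statistic: float
    pvalue: float
    kind: str
    table: pd.DataFrame | None = None


def compare_methods(results: pd.DataFrame, comparison: str = "paired_t",
                    factor: str = "method") -> ComparisonResult:
    """Test for a difference between two conditions.

    paired_t pairs the accuracies of exactly two levels of ``factor``
    within each validation set (the six-set layout).  anova fits a
    fixed-effects linear model with the condition, validation set and SNP
    replicate as factors and F-tests the condition factor (no
    interactions).
    """
    levels = list(pd.unique(results[factor]))
    if comparison == "paired_t":
        if len(levels) != 2:
            raise ValueError("paired_t needs exactly two conditions")
        wide = results.pivot_table(index="set", columns=factor,
                                   values="accuracy", aggfunc="mean")
        if wide.isna().any().any():
            raise ValueError("unpaired input: a set lacks one condition")
        d = wide[levels[0]] - wide[levels[1]]
        if np.allclose(d, 0):
            return ComparisonResult(0.0, 1.0, "paired_t")
        t = scipy.stats.ttest_rel(wide[levels[0]], wide[levels[1]])
        return ComparisonResult(float(t.statistic), float(t.pvalue), "paired_t")
    if comparison == "anova":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        df = results.copy()
        df["accuracy"] = df["accuracy"].astype(float)
        terms = [f"C({factor})", "C(set)"]
        if df.groupby(factor)["replicate"].nunique().max() > 1:
            terms.append("C(replicate)")
        model = smf.ols("accuracy ~ " + " + ".join(terms), data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        row = tab.loc[f"C({factor})"]
        return ComparisonResult(float(row["F"]), float(row["PR(>F)"]),
                                "anova", tab)
    raise ValueError(f"unknown comparison {comparison!r}")


@dataclass
class ValueSummary:
    cv: dict[str, float]
    skewness: dict[str, float]
    between_site_correlation: float | None
    n_shared: int


def adjusted_value_summary(site_values: dict[str, pd.Series]) -> ValueSummary:
    """CV, adjusted Fisher-Pearson skewness per site, and the Pearson
    correlation of the design-adjusted cross values over shared crosses."""
    cv, skew = {}, {}
    for site, v in site_values.items():
        if len(v) < 3:
            raise ValueError("need at least three crosses per site")
        m = float(v.mean())
        if m == 0:
            raise ValueError(f"zero mean for site {site}; CV undefined")
        cv[site] = float(v.std(ddof=1)) / m
        s = v.to_numpy(float)
        skew[site] = (0.0 if np.std(s) == 0
                      else float(scipy.stats.skew(s, bias=False)))
    corr, n_shared = None, 0
    if len(site_values) == 2:
        a, b = site_values.values()
        shared = a.index.intersection(b.index)
        n_shared = len(shared)
        if n_shared >= 3:
            corr = float(scipy.stats.pearsonr(a[shared], b[shared]).statistic)
    return ValueSummary(cv, skew, corr, n_shared)
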