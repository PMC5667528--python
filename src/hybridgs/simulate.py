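"""Synthetic two-group hybrid breeding data.

Emulates the statistical structure the downstream analysis assumes: two
heterotic parental populations descending from a handful of founders with
routine selfing and mating among relatives; unlinked biallelic SNPs with
GBS-like per-call depth and per-SNP missingness; an incomplete-factorial
A x B mating design; and hybrid phenotypes generated under the GCA/SCA
mixed-model variance structure (trial/block/age fixed effects, plot,
individual, age-by-cross and residual random effects), with true GCAs built
from additive SNP effects so the markers carry real signal.

Loci segregate independently (no linkage map): none of the downstream
analyses use linkage, and the marker summary distributions do not require it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (GenotypeTable, MatingDesign, Pedigree, PHENOTYPE_COLUMNS,
                   RelationshipMatrix, UNKNOWN_PARENT)
from .relmat import dominance_gamma, pedigree_relationship


@dataclass
class PopulationSpec:
    """Parameters of one parental breeding population.

    Founder alternate-allele frequencies are drawn from a Beta distribution
    (right-skewed MAF histogram, as is typical of GBS data) unless
    ``founder_freq`` pins a single frequency for all SNPs.  Depth per data
    point follows a long-tailed mixed Poisson (per-SNP lognormal mean, mean
    around 70 reads); per-SNP missingness rates follow a right-skewed Beta
    with mean around 0.13.
    """

    group_label: str
    n_founders: int = 4
    n_generations: int = 3
    selfing_prob: float = 0.2
    mating_related_prob: float = 0.3
    n_individuals_per_generation: int = 30
    n_snps: int = 500
    seed: int = 0
    founder_freq: float | None = None
    founder_beta: tuple[float, float] = (1.2, 4.0)
    depth_mean: float = 70.0
    depth_log_sd: float = 0.6
    missing_beta: tuple[float, float] = (0.6, 4.0)
    genotyping_error_rate: float = 0.0
    gbs_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least two founders")
        if self.n_generations < 0:
            raise ValueError("n_generations must be non-negative")
        for p in (self.selfing_prob, self.mating_related_prob,
                  self.genotyping_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def simulate_breeding_population(spec: PopulationSpec
                                 ) -> tuple[Pedigree, GenotypeTable]:
    """Gene-drop a breeding population and observe it through a GBS screen.

    Founders carry Hardy-Weinberg genotypes at the founder frequencies;
    each later generation is produced by selfing (probability
    ``selfing_prob``) or by mating, preferring a relative of the first
    parent with probability ``mating_related_prob``.  With
    ``gbs_noise=True`` dosages are masked to missing per a per-SNP rate and
    every call gets a simulated read depth; dosages before masking are
    Mendelian-consistent by construction.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.group_label
    if spec.founder_freq is not None:
        p = np.full(spec.n_snps, float(spec.founder_freq))
    else:
        a, b = spec.founder_beta
        p = rng.beta(a, b, spec.n_snps)
        p = np.clip(p, 0.01, 0.99)

    ids: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    gens: list[int] = []
    dosages: list[np.ndarray] = []
    parent_key: dict[str, tuple[str, str]] = {}

    def add(iid, s, d, gen, dose):
        ids.append(iid); sires.append(s); dams.append(d); gens.append(gen)
        dosages.append(dose)
        parent_key[iid] = tuple(sorted((s, d)))

    for k in range(spec.n_founders):
        dose = rng.binomial(1, p) + rng.binomial(1, p)
        add(f"{g}F{k}", UNKNOWN_PARENT, UNKNOWN_PARENT, 0, dose.astype(float))

    prev = list(ids)
    prev_dose = {i: d for i, d in zip(ids, dosages)}
    for gen in range(1, spec.n_generations + 1):
        cur: list[str] = []
        cur_dose: dict[str, np.ndarray] = {}
        for k in range(spec.n_individuals_per_generation):
            p1 = prev[rng.integers(len(prev))]
            if len(prev) == 1 or rng.random() < spec.selfing_prob:
                p2 = p1
            elif rng.random() < spec.mating_related_prob:
                sibs = [i for i in prev
                        if i != p1 and parent_key[i] == parent_key[p1]]
                p2 = sibs[rng.integers(len(sibs))] if sibs else \
                    _other(prev, p1, rng)
            else:
                p2 = _other(prev, p1, rng)
            # one gamete per parent; at a single unlinked locus a random
            # allele is Bernoulli(dosage/2)
            gam1 = rng.random(spec.n_snps) < prev_dose[p1] / 2.0
            gam2 = rng.random(spec.n_snps) < prev_dose[p2] / 2.0
            dose = gam1.astype(float) + gam2.astype(float)
            iid = f"{g}G{gen}I{k}"
            add(iid, p1, p2, gen, dose)
            cur.append(iid)
            cur_dose[iid] = dose
        prev, prev_dose = cur, cur_dose

    D = np.vstack(dosages)
    n = len(ids)
    if spec.genotyping_error_rate > 0:
        err = rng.random(D.shape) < spec.genotyping_error_rate
        shift = rng.integers(1, 3, size=D.shape)
        D = np.where(err, (D + shift) % 3, D)
    mu_snp = np.exp(rng.normal(np.log(spec.depth_mean) - spec.depth_log_sd**2 / 2,
                               spec.depth_log_sd, spec.n_snps))
    depth = rng.poisson(np.broadcast_to(mu_snp, (n, spec.n_snps))).astype(float)
    if spec.gbs_noise:
        miss_rate = rng.beta(*spec.missing_beta, spec.n_snps)
        miss = rng.random(D.shape) < miss_rate
        D = np.where(miss, np.nan, D)
        depth = np.where(miss, rng.integers(0, 5, size=depth.shape), depth)

    ped = Pedigree(pd.DataFrame({
        "id": ids, "sire": sires, "dam": dams,
        "group": g, "generation": gens,
    }))
    snps = pd.DataFrame({
        "snp_id": [f"snp{j}" for j in range(spec.n_snps)],
        "chrom": [str(1 + j % 16) for j in range(spec.n_snps)],
        "pos": [1000 * (j + 1) for j in range(spec.n_snps)],
        "ref": "A", "alt": "T",
    })
    gt = GenotypeTable(ids=ids, snps=snps, dosage=D, depth=depth,
                       groups=np.array([g] * n, dtype=object))
    return ped, gt


def _other(pool, first, rng):
    while True:
        cand = pool[rng.integers(len(pool))]
        if cand != first or len(pool) == 1:
            return cand


def simulate_mating_design(parents_a: list[str], parents_b: list[str],
                           crosses_per_parent: int, seed: int = 0) -> MatingDesign:
    """Incomplete factorial: every parent used 1..crosses_per_parent times.

    When ``crosses_per_parent`` covers the opposite group entirely the
    design saturates to the full factorial; otherwise each parent is
    allotted a uniform number of crosses up to the bound and stubs are
    matched at random, repairing duplicate pairs.
    """
    if not parents_a or not parents_b:
        raise ValueError("both parent lists must be non-empty")
    if crosses_per_parent < 1:
        raise ValueError("crosses_per_parent must be >= 1")
    rng = np.random.default_rng(seed)
    na, nb = len(parents_a), len(parents_b)
    if crosses_per_parent >= max(na, nb):
        pairs = [(a, b) for a in parents_a for b in parents_b]
    else:
        da = rng.integers(1, crosses_per_parent + 1, na)
        total = int(np.clip(da.sum(), nb, nb * crosses_per_parent))
        # rescale A degrees to the feasible total
        while da.sum() > total:
            k = rng.integers(na)
            if da[k] > 1:
                da[k] -= 1
        while da.sum() < total:
            k = rng.integers(na)
            if da[k] < crosses_per_parent:
                da[k] += 1
        db = np.ones(nb, dtype=int)
        extra = total - nb
        while extra > 0:
            k = rng.integers(nb)
            if db[k] < crosses_per_parent:
                db[k] += 1
                extra -= 1
        stubs_a = np.repeat(np.array(parents_a, dtype=object), da)
        stubs_b = np.repeat(np.array(parents_b, dtype=object), db)
        rng.shuffle(stubs_a)
        rng.shuffle(stubs_b)
        pairs = list(zip(stubs_a, stubs_b))
        pairs = _repair_duplicates(pairs, rng)
    df = pd.DataFrame({
        "cross": [f"X{a}x{b}" for a, b in pairs],
        "parent_a": [a for a, _ in pairs],
        "parent_b": [b for _, b in pairs],
    })
    return MatingDesign(df)


def _repair_duplicates(pairs, rng, max_sweeps: int = 50):
    for _ in range(max_sweeps):
        seen: dict[tuple, int] = {}
        dup_idx = []
        for k, pr in enumerate(pairs):
            if pr in seen:
                dup_idx.append(k)
            else:
                seen[pr] = k
        if not dup_idx:
            return pairs
        for k in dup_idx:
            j = int(rng.integers(len(pairs)))
            a_k, b_k = pairs[k]
            a_j, b_j = pairs[j]
            pairs[k], pairs[j] = (a_k, b_j), (a_j, b_k)
    # drop residual duplicates; each endpoint of a duplicate still has >= 1 use
    seen = set()
    out = []
    for pr in pairs:
        if pr not in seen:
            seen.add(pr)
            out.append(pr)
    return out


@dataclass
class SimVarianceComponents:
    """Generating variance components on the phenotype scale (trait units^2)."""

    mean: float = 120.9
    var_gca_a: float = 25.0
    var_gca_b: float = 55.0
    var_sca: float = 5.0
    var_plot: float = 10.0
    var_individual: float = 30.0
    var_age_cross: float = 5.0
    var_error: float = 80.0
    var_incomplete_block: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if name != "mean" and v < 0:
                raise ValueError(f"negative variance {name}")


@dataclass
class TrialLayout:
    """Field-trial layout: randomized complete blocks, optionally a lattice."""

    n_trials: int = 2
    n_blocks: int = 5
    palms_per_plot: int = 4
    ages: tuple[int, ...] = (3, 4, 5, 6, 7)
    lattice: bool = False
    incomplete_blocks_per_block: int = 4
    trial_sd: float = 5.0
    block_sd: float = 2.0
    age_profile: dict[int, float] | None = None


@dataclass
class TrueGeneticValues:
    """The generating GCAs and SCAs behind a simulated phenotype table."""

    gca_a: pd.Series
    gca_b: pd.Series
    sca: pd.Series
    components: SimVarianceComponents
    marker_effects_a: np.ndarray | None = None
    marker_effects_b: np.ndarray | None = None

    def cross_values(self, design: MatingDesign) -> pd.Series:
        pm = design.parent_map()
        vals = {c: self.gca_a[a] + self.gca_b[b] + self.sca[c]
                for c, (a, b) in pm.items()}
        return pd.Series(vals, name="true_cross_value")


def simulate_phenotypes(design: MatingDesign, pedigree_a: Pedigree,
                        pedigree_b: Pedigree, genotypes: GenotypeTable,
                        components: SimVarianceComponents,
                        layout: TrialLayout | None = None,
                        seed: int = 0, trait: str = "FFB",
                        ) -> tuple[pd.DataFrame, TrueGeneticValues]:
    """Phenotypes of hybrid individuals under the GCA/SCA variance structure.

    True GCAs are sums of per-group additive SNP effects (rescaled so their
    sample variance equals the requested component), so markers genuinely
    carry the signal; SCAs are multivariate normal with the cross-level
    dominance covariance implied by the pedigrees; trial, block and age act
    as fixed effects, and plot / individual / age-by-cross / residual as
    independent normal deviates.
    """
    layout = layout or TrialLayout()
    rng = np.random.default_rng(seed)
    pm = design.parent_map()
    pa = design.parents_a
    pb = design.parents_b
    gen_ids = set(genotypes.ids)
    for c, (a, b) in pm.items():
        if a not in gen_ids or b not in gen_ids:
            raise ValueError(f"cross {c!r} references an ungenotyped parent")

    gca_a, beta_a = _marker_gcas(genotypes, pa, components.var_gca_a, rng)
    gca_b, beta_b = _marker_gcas(genotypes, pb, components.var_gca_b, rng)

    cross_ids = design.cross_ids
    if components.var_sca > 0:
        ga = pedigree_relationship(pedigree_a, pa)
        gb = pedigree_relationship(pedigree_b, pb)
        half_a = RelationshipMatrix(ga.ids, 0.5 * ga.values, ga.kind)
        half_b = RelationshipMatrix(gb.ids, 0.5 * gb.values, gb.kind)
        GD = dominance_gamma(half_a, half_b, design).values
        L = np.linalg.cholesky(GD + 1e-10 * np.eye(len(GD)))
        sca_vals = np.sqrt(components.var_sca) * (L @ rng.standard_normal(len(GD)))
    else:
        sca_vals = np.zeros(len(cross_ids))
    sca = pd.Series(sca_vals, index=cross_ids)

    age_profile = layout.age_profile or {a: 1.5 * (a - np.mean(layout.ages))
                                         for a in layout.ages}
    trial_eff = rng.normal(0, layout.trial_sd, layout.n_trials)
    rows = []
    # crosses divided among trials; each cross appears once per block
    trial_of = {c: k % layout.n_trials for k, c in enumerate(cross_ids)}
    sd = components
    for c in cross_ids:
        t = trial_of[c]
        a_par, b_par = pm[c]
        genetic = gca_a[a_par] + gca_b[b_par] + sca[c]
        age_dev = rng.normal(0, np.sqrt(sd.var_age_cross), len(layout.ages))
        for blk in range(layout.n_blocks):
            block_eff = rng.normal(0, layout.block_sd)
            iblk = (rng.integers(layout.incomplete_blocks_per_block)
                    if layout.lattice else None)
            iblk_eff = (rng.normal(0, np.sqrt(sd.var_incomplete_block))
                        if layout.lattice else 0.0)
            plot_id = f"T{t}B{blk}{c}"
            plot_eff = rng.normal(0, np.sqrt(sd.var_plot))
            for palm in range(layout.palms_per_plot):
                ind_id = f"{plot_id}P{palm}"
                ind_eff = rng.normal(0, np.sqrt(sd.var_individual))
                for ai, age in enumerate(layout.ages):
                    e = rng.normal(0, np.sqrt(sd.var_error))
                    y = (sd.mean + trial_eff[t] + block_eff + iblk_eff
                         + age_profile[age] + genetic + age_dev[ai]
                         + plot_eff + ind_eff + e)
                    rows.append((c, f"T{t}", f"T{t}B{blk}",
                                 None if iblk is None else f"T{t}B{blk}Q{iblk}",
                                 plot_id, ind_id, age, trait, y))
    phen = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    truth = TrueGeneticValues(gca_a=gca_a, gca_b=gca_b, sca=sca,
                              components=components,
                              marker_effects_a=beta_a, marker_effects_b=beta_b)
    return phen, truth


def _marker_gcas(genotypes: GenotypeTable, parents: list[str],
                 var_target: float, rng) -> tuple[pd.Series, np.ndarray | None]:
    if var_target == 0:
        return pd.Series(0.0, index=parents), None
    sub = genotypes.subset(parents)
    D = sub.dosage.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(np.where(np.isnan(D), np.nan, D), axis=0)
    col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
    inds = np.where(np.isnan(D))
    D[inds] = np.take(col_mean, inds[1])
    W = D - D.mean(axis=0)
    beta = rng.standard_normal(W.shape[1])
    raw = W @ beta
    s = raw.std(ddof=1)
    if s == 0:
        raw = rng.standard_normal(len(parents))
        s = raw.std(ddof=1)
        beta = None
    g = raw * np.sqrt(var_target) / s
    return pd.Series(g, index=parents), beta
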