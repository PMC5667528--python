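"""Post-calling SNP quality control for GBS genotype tables.

Filter chain (fixed order, counts reported per stage): per-call depth mask,
biallelic-SNV requirement, per-site missingness, mean-depth outliers
(suspected genome duplications), unmapped sites, then Mendelian-consistency
checks against the pedigree.  Thresholds follow common GBS practice for
breeding populations: calls under 5 reads are unreliable, sites over 50%
missing or with mean depth above 500 are dropped, and sites homozygous in a
parental group or with more than 5% Mendelian inconsistencies are dropped
from that group.  "More than" is strict at equality throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeTable, Pedigree


@dataclass
class FilterConfig:
    min_depth: int = 5
    max_site_missing: float = 0.5
    max_mean_depth: float = 500.0
    max_mendelian_inconsistency: float = 0.05
    require_biallelic_snv: bool = True
    require_mapped: bool = True
    low_missing_threshold: float = 0.05

    def __post_init__(self) -> None:
        for f in (self.max_site_missing, self.max_mendelian_inconsistency,
                  self.low_missing_threshold):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.min_depth < 0 or self.max_mean_depth < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class QCReport:
    """Per-stage site/call counts and per-SNP summary statistics."""

    input_sites: int = 0
    masked_low_depth_calls: int = 0
    dropped_non_biallelic: int = 0
    dropped_missingness: int = 0
    dropped_mean_depth: int = 0
    dropped_unmapped: int = 0
    masked_mendelian_calls: int = 0
    dropped_mendelian: dict[str, int] = field(default_factory=dict)
    retained_sites: int = 0
    snp_stats: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("snp_stats", "dropped_mendelian")}
        for g, n in self.dropped_mendelian.items():
            d[f"dropped_mendelian_{g}"] = n
        return pd.DataFrame({"count": d})


def apply_site_filters(genotypes: GenotypeTable,
                       config: FilterConfig | None = None
                       ) -> tuple[GenotypeTable, QCReport]:
    """Depth mask and site-level filters, in the documented order."""
    config = config or FilterConfig()
    rep = QCReport(input_sites=genotypes.n_snps)
    D = genotypes.dosage.copy()
    depth = None if genotypes.depth is None else genotypes.depth.copy()
    if config.min_depth > 0:
        if depth is None:
            raise ValueError("depth matrix required when min_depth > 0")
        low = ~np.isnan(depth) & (depth < config.min_depth) & ~np.isnan(D)
        rep.masked_low_depth_calls = int(low.sum())
        D = np.where(low, np.nan, D)

    keep = np.ones(genotypes.n_snps, dtype=bool)
    snps = genotypes.snps
    if config.require_biallelic_snv and {"ref", "alt"} <= set(snps.columns):
        ref = snps["ref"].astype(str)
        alt = snps["alt"].astype(str)
        bi = (ref.str.len() == 1) & (alt.str.len() == 1) & \
             ~alt.str.contains(",") & (ref != alt)
        rep.dropped_non_biallelic = int((~bi & keep).sum())
        keep &= bi.to_numpy()

    miss = np.isnan(D).mean(axis=0)
    too_missing = miss > config.max_site_missing
    rep.dropped_missingness = int((too_missing & keep).sum())
    keep &= ~too_missing

    if depth is not None:
        with np.errstate(invalid="ignore"):
            mean_depth = np.nanmean(np.where(np.isnan(depth), np.nan, depth), axis=0)
        too_deep = np.nan_to_num(mean_depth) > config.max_mean_depth
        rep.dropped_mean_depth = int((too_deep & keep).sum())
        keep &= ~too_deep

    if config.require_mapped and "chrom" in snps.columns:
        unmapped = snps["chrom"].astype(str).isin(("", ".", "0", "un", "Un")).to_numpy()
        rep.dropped_unmapped = int((unmapped & keep).sum())
        keep &= ~unmapped

    kept_ids = list(snps.loc[keep, "snp_id"])
    out = GenotypeTable(
        ids=genotypes.ids,
        snps=snps.loc[keep].reset_index(drop=True),
        dosage=D[:, keep],
        depth=None if depth is None else depth[:, keep],
        groups=genotypes.groups,
    )
    rep.retained_sites = len(kept_ids)
    return out, rep


def _impossible(child: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Boolean per-locus mask: child dosage unattainable from parents.

    Trios: impossible iff the child needs an allele neither transmitting
    parent can give (sire 0 cannot give alt, sire 2 cannot give ref, etc.).
    Loci with a missing call anywhere are never flagged; with a single known
    parent (NaN co-parent) only that duo's constraint applies.
    """
    c = child
    bad = np.zeros(c.shape, dtype=bool)
    both = ~np.isnan(c) & ~np.isnan(sire) & ~np.isnan(dam)
    # minimum alt alleles the pair must transmit: (s>0 unknown -> 0);
    # a parent with dosage 2 must transmit alt, dosage 0 must transmit ref
    min_alt = (sire == 2).astype(int) + (dam == 2).astype(int)
    max_alt = 2 - (sire == 0).astype(int) - (dam == 0).astype(int)
    bad |= both & ((c < min_alt) | (c > max_alt))
    for par in (sire, dam):
        duo = ~np.isnan(c) & ~np.isnan(par)
        bad |= duo & (par == 2) & (c == 0)
        bad |= duo & (par == 0) & (c == 2)
    return bad


def mendelian_filter(genotypes: GenotypeTable, pedigree: Pedigree,
                     config: FilterConfig | None = None
                     ) -> tuple[GenotypeTable, QCReport]:
    """Mask Mendelian-inconsistent calls; drop bad or monomorphic sites.

    Offspring calls impossible given the non-missing parental calls are set
    to missing.  Then, per parental group, sites that are homozygous
    (monomorphic among called genotypes) or whose inconsistency fraction
    exceeds ``max_mendelian_inconsistency`` are dropped from that group's
    retained list; a site survives the table if it survives in at least one
    group.  Unknown or ungenotyped parents skip the check.
    """
    config = config or FilterConfig()
    rep = QCReport(input_sites=genotypes.n_snps)
    D = genotypes.dosage.copy()
    pos = {i: k for k, i in enumerate(genotypes.ids)}
    nan_row = np.full(genotypes.n_snps, np.nan)

    checked = np.zeros(D.shape, dtype=bool)
    bad_all = np.zeros(D.shape, dtype=bool)
    in_ped = set(pedigree.ids)
    for iid in genotypes.ids:
        if iid not in in_ped:
            continue
        s, d = pedigree.parents(iid)
        srow = D[pos[s]] if (s in pos if s else False) else nan_row
        drow = D[pos[d]] if (d in pos if d else False) else nan_row
        if np.isnan(srow).all() and np.isnan(drow).all():
            continue
        r = pos[iid]
        bad = _impossible(D[r], srow, drow)
        bad_all[r] = bad
        checked[r] = ~np.isnan(D[r]) & (~np.isnan(srow) | ~np.isnan(drow))
    rep.masked_mendelian_calls = int(bad_all.sum())
    D = np.where(bad_all, np.nan, D)

    groups = (genotypes.groups if genotypes.groups is not None
              else np.array(["all"] * genotypes.n_individuals, dtype=object))
    retained_per_group: dict[str, np.ndarray] = {}
    for g in pd.unique(groups):
        rows = np.flatnonzero(groups == g)
        sub = D[rows]
        called = ~np.isnan(sub)
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mono = np.array([
                len(np.unique(sub[:, j][called[:, j]])) <= 1 if n_called[j] > 0 else True
                for j in range(sub.shape[1])])
            nchk = checked[rows].sum(axis=0)
            frac_bad = np.where(nchk > 0, bad_all[rows].sum(axis=0) / np.maximum(nchk, 1), 0.0)
        ok = ~mono & (frac_bad <= config.max_mendelian_inconsistency)
        retained_per_group[g] = ok
        rep.dropped_mendelian[str(g)] = int((~ok).sum())
    keep = np.any(np.vstack(list(retained_per_group.values())), axis=0)
    out = GenotypeTable(
        ids=genotypes.ids,
        snps=genotypes.snps.loc[keep].reset_index(drop=True),
        dosage=D[:, keep],
        depth=None if genotypes.depth is None else genotypes.depth[:, keep],
        groups=genotypes.groups,
    )
    rep.retained_sites = int(keep.sum())
    snp_ids = genotypes.snps["snp_id"].to_numpy()
    rep.snp_stats = pd.DataFrame({
        f"retained_{g}": pd.Series(v, index=snp_ids)
        for g, v in retained_per_group.items()})
    return out, rep


def marker_stats(genotypes: GenotypeTable) -> QCReport:
    """Per-SNP MAF, missingness and mean depth, with group-level means."""
    D = genotypes.dosage
    called = ~np.isnan(D)
    miss = 1.0 - called.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(D, axis=0) / 2.0
        if genotypes.depth is not None:
            mean_depth = np.nanmean(np.where(np.isnan(genotypes.depth), np.nan,
                                             genotypes.depth), axis=0)
        else:
            mean_depth = np.full(genotypes.n_snps, np.nan)
    maf = np.minimum(p, 1.0 - p)
    stats = pd.DataFrame({
        "snp_id": genotypes.snps["snp_id"],
        "maf": maf,
        "missingness": miss,
        "mean_depth": mean_depth,
    })
    rep = QCReport(input_sites=genotypes.n_snps, retained_sites=genotypes.n_snps,
                   snp_stats=stats)
    return rep


def subsample_snps(genotypes: GenotypeTable, n: int,
                   strategy: str = "random", seed: int = 0) -> list[str]:
    """Choose ``n`` SNP ids, uniformly at random or by lowest missingness.

    ``min_missing`` is deterministic: ties on missingness are broken by
    higher MAF, then genome order (chrom, pos).
    """
    if n > genotypes.n_snps:
        raise ValueError(f"requested {n} SNPs but only {genotypes.n_snps} available")
    ids = genotypes.snps["snp_id"].to_numpy()
    if strategy == "random":
        rng = np.random.default_rng(seed)
        return list(ids[np.sort(rng.choice(genotypes.n_snps, n, replace=False))])
    if strategy == "min_missing":
        stats = marker_stats(genotypes).snp_stats
        order = stats.assign(order=np.arange(len(stats))).sort_values(
            ["missingness", "maf", "order"], ascending=[True, False, True],
            kind="stable")
        return list(order["snp_id"].iloc[:n])
    raise ValueError(f"unknown strategy {strategy!r}")


def naive_impute(genotypes: GenotypeTable,
                 pedigree: Pedigree | None = None) -> GenotypeTable:
    """Fill missing dosages; a simple deterministic imputer.

    With a pedigree and both parents called at the site, the fill is the
    most probable transmitted dosage (rounded Mendelian expectation);
    otherwise the per-SNP within-group mean, rounded to an admissible value.
    The output contains no missing cells.
    """
    D = genotypes.dosage.copy()
    pos = {i: k for k, i in enumerate(genotypes.ids)}
    if pedigree is not None:
        for iid in genotypes.ids:
            if iid not in set(pedigree.ids):
                continue
            s, d = pedigree.parents(iid)
            if s is None or d is None or s not in pos or d not in pos:
                continue
            r = pos[iid]
            todo = np.isnan(D[r]) & ~np.isnan(D[pos[s]]) & ~np.isnan(D[pos[d]])
            if todo.any():
                expect = (D[pos[s]][todo] + D[pos[d]][todo]) / 2.0
                D[r, np.flatnonzero(todo)] = np.round(expect)
    groups = (genotypes.groups if genotypes.groups is not None
              else np.array(["all"] * genotypes.n_individuals, dtype=object))
    for g in pd.unique(groups):
        rows = np.flatnonzero(groups == g)
        sub = D[rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(sub, axis=0)
        col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
        fill = np.clip(np.round(col_mean), 0, 2)
        inds = np.where(np.isnan(sub))
        sub[inds] = np.take(fill, inds[1])
        D[rows] = sub
    return GenotypeTable(ids=genotypes.ids, snps=genotypes.snps.copy(),
                         dosage=D, depth=None if genotypes.depth is None
                         else genotypes.depth.copy(), groups=genotypes.groups)
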