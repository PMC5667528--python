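"""GCA/SCA linear mixed model for two-group hybrid crosses.

The phenotype of a hybrid individual is modelled as

    Y = X beta + Z b + Z_A g_A + Z_B g_B + Z_D s_AB + e

with fixed experimental-design effects (overall mean, trial, block and, for
production traits, age), random design effects b (elementary plot,
individual, age-by-cross and, in lattice trials, incomplete block), the
GCAs g_A ~ N(0, sigma2_gA Gamma_A) and g_B ~ N(0, sigma2_gB Gamma_B) of the
two parental groups, and the SCAs s_AB ~ N(0, sigma2_d Gamma_D) of the
crosses.  The age-by-cross interaction has covariance I (x) Gamma_D (age
outer, cross inner).  Plugging identity, pedigree (0.5 A) or combined
pedigree-genomic matrices into the Gamma slots yields the TBLUP, PBLUP and
GBLUP variants of the same model.

Solutions come from Henderson's mixed-model equations; variance components
from restricted maximum likelihood, either EM steps or average-information
updates with an EM fallback.  Prediction error variances are read off the
inverse coefficient matrix and convert to individual selection accuracies
as sqrt(1 - PEV / (Gamma_ii sigma2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .core import (GammaStructure, GenotypeTable, MatingDesign, Pedigree,
                   RelationshipMatrix)
from .relmat import dominance_gamma, pedigree_relationship

GENETIC_TERMS = ("gA", "gB", "sAB")


@dataclass
class ModelSpec:
    """What enters the model besides the always-present genetic terms."""

    trait: str | None = None
    include_age_by_cross: bool = True
    include_individual: bool = True
    include_plot: bool = True


@dataclass
class RandomTerm:
    name: str
    Z: np.ndarray
    levels: list[str]
    Ginv: np.ndarray | None = None  # None = identity covariance
    gamma_diag: np.ndarray | None = None  # diag of Gamma, for PEV accuracy

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class MMESystem:
    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    terms: list[RandomTerm]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def term(self, name: str) -> RandomTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class VarianceComponents:
    """One sigma^2 per random term plus the residual variance."""

    by_term: dict[str, float]
    residual: float

    def __post_init__(self) -> None:
        if self.residual <= 0:
            raise ValueError("residual variance must be positive")
        for k, v in self.by_term.items():
            if v < 0:
                raise ValueError(f"negative variance for term {k}")

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(dict(self.by_term), self.residual)


@dataclass
class MixedModelFit:
    beta: pd.Series
    solutions: dict[str, pd.Series]
    pev: dict[str, pd.Series]
    vc: VarianceComponents
    loglik: float | None = None
    converged: bool = True
    mme_residual: float = 0.0
    gamma_diag: dict[str, pd.Series] = field(default_factory=dict)

    def cross_values(self, design: MatingDesign, with_sca: bool = True
                     ) -> "CrossValuePrediction":
        """Predicted value per cross: gA(a) + gB(b) (+ sAB(ab))."""
        ga, gb = self.solutions["gA"], self.solutions["gB"]
        s = self.solutions.get("sAB")
        vals = {}
        for r in design.crosses.itertuples(index=False):
            v = ga[r.parent_a] + gb[r.parent_b]
            if with_sca:
                if s is None:
                    raise ValueError("no SCA term in this fit")
                v += s[r.cross]
            vals[r.cross] = v
        return CrossValuePrediction(pd.Series(vals, name="cross_value"), with_sca)


@dataclass
class CrossValuePrediction:
    values: pd.Series
    with_sca: bool


def _dummies(labels: pd.Series, drop_first_within: pd.Series | None = None,
             prefix: str = "") -> tuple[np.ndarray, list[str]]:
    """Reference-constrained dummy coding (first level dropped).

    With ``drop_first_within`` the first level is dropped inside each group
    of the nesting factor, avoiding collinearity of nested factors.
    """
    labels = labels.astype(str)
    if drop_first_within is None:
        levels = list(pd.unique(labels))
        keep = levels[1:]
    else:
        keep = []
        for _, sub in labels.groupby(drop_first_within.astype(str), sort=False):
            lv = list(pd.unique(sub))
            keep.extend(lv[1:])
    cols = np.column_stack([(labels == lv).to_numpy(float) for lv in keep]) \
        if keep else np.empty((len(labels), 0))
    return cols, [f"{prefix}{lv}" for lv in keep]


def _incidence(labels: pd.Series, levels: list[str]) -> np.ndarray:
    pos = {lv: k for k, lv in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for i, lv in enumerate(labels.astype(str)):
        Z[i, pos[lv]] = 1.0
    return Z


def _ginv(values: np.ndarray) -> np.ndarray:
    n = len(values)
    try:
        L = np.linalg.cholesky(values)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(values + 1e-8 * np.trace(values) / n * np.eye(n))
    Li = np.linalg.inv(L)
    return Li.T @ Li


def build_design(phenotypes: pd.DataFrame, design: MatingDesign,
                 gammas: GammaStructure, spec: ModelSpec | None = None
                 ) -> MMESystem:
    """Assemble Y, X and the random-term incidence/covariance structure.

    ``gammas`` may cover more parents/crosses than appear in the phenotypes
    (unphenotyped validation individuals get BLUPs through the covariance).
    Incomplete block and elementary plot are treated as nested in block and
    trial by using their fully-qualified labels.
    """
    spec = spec or ModelSpec()
    df = phenotypes.copy()
    if spec.trait is not None:
        df = df[df["trait"] == spec.trait]
    if df.empty:
        raise ValueError("no phenotype rows for the requested trait")
    known = set(design.cross_ids)
    bad = set(df["cross"].astype(str)) - known
    if bad:
        raise ValueError(f"phenotypes reference unknown crosses {sorted(bad)[:4]}")
    df = df.reset_index(drop=True)
    y = df["value"].to_numpy(float)

    X_parts = [np.ones((len(df), 1))]
    names = ["mu"]
    if df["trial"].nunique() > 1:
        C, nm = _dummies(df["trial"], prefix="trial:")
        X_parts.append(C); names.extend(nm)
    if df["block"].nunique() > 1:
        C, nm = _dummies(df["block"], drop_first_within=df["trial"], prefix="block:")
        X_parts.append(C); names.extend(nm)
    has_age = df["age"].notna().all() and df["age"].nunique() > 1
    if has_age:
        C, nm = _dummies(df["age"].astype(int).astype(str), prefix="age:")
        X_parts.append(C); names.extend(nm)
    X = np.hstack(X_parts)

    terms: list[RandomTerm] = []
    if spec.include_plot and df["plot"].notna().all():
        levels = list(pd.unique(df["plot"].astype(str)))
        if len(levels) < len(df):
            terms.append(RandomTerm("plot", _incidence(df["plot"], levels), levels))
    if df["incomplete_block"].notna().all() and df["incomplete_block"].nunique() > 1:
        levels = list(pd.unique(df["incomplete_block"].astype(str)))
        terms.append(RandomTerm("incomplete_block",
                                _incidence(df["incomplete_block"], levels), levels))
    if spec.include_individual and df["individual"].notna().all():
        levels = list(pd.unique(df["individual"].astype(str)))
        if len(levels) < len(df):
            terms.append(RandomTerm("individual",
                                    _incidence(df["individual"], levels), levels))

    pm = design.parent_map()
    cross_of = df["cross"].astype(str)
    ga, gb, gd = gammas.gamma_a, gammas.gamma_b, gammas.gamma_d
    a_of = cross_of.map({c: ab[0] for c, ab in pm.items()})
    b_of = cross_of.map({c: ab[1] for c, ab in pm.items()})
    terms.append(RandomTerm("gA", _incidence(a_of, ga.ids), list(ga.ids),
                            _ginv(ga.values), np.diag(ga.values).copy()))
    terms.append(RandomTerm("gB", _incidence(b_of, gb.ids), list(gb.ids),
                            _ginv(gb.values), np.diag(gb.values).copy()))
    if gd is not None:
        terms.append(RandomTerm("sAB", _incidence(cross_of, gd.ids),
                                list(gd.ids), _ginv(gd.values),
                                np.diag(gd.values).copy()))
        if spec.include_age_by_cross and has_age:
            ages = sorted(df["age"].astype(int).unique())
            levels = [f"a{a}|{c}" for a in ages for c in gd.ids]
            lab = "a" + df["age"].astype(int).astype(str) + "|" + cross_of
            GDinv = _ginv(gd.values)
            Ginv = np.kron(np.eye(len(ages)), GDinv)
            gdiag = np.tile(np.diag(gd.values), len(ages))
            terms.append(RandomTerm("age_cross", _incidence(lab, levels),
                                    levels, Ginv, gdiag))
    return MMESystem(y=y, X=X, fixed_names=names, terms=terms)


def solve_mme(system: MMESystem, vc: VarianceComponents,
              compute_pev: bool = True) -> MixedModelFit:
    """Solve Henderson's mixed-model equations at fixed variance components.

    Returns BLUEs, BLUPs and, from the inverse coefficient matrix, the
    prediction error variance of every genetic-term level.
    """
    se2 = vc.residual
    blocks = [system.X] + [t.Z for t in system.terms]
    W = np.hstack(blocks)
    C = W.T @ W
    rhs = W.T @ system.y
    p = system.X.shape[1]
    off = p
    slices: dict[str, slice] = {}
    for t in system.terms:
        q = t.n_levels
        sl = slice(off, off + q)
        slices[t.name] = sl
        s2 = vc.by_term.get(t.name, 0.0)
        if s2 <= 0:
            raise ValueError(f"variance for term {t.name!r} must be positive "
                             "to enter the MME (drop the term instead)")
        lam = se2 / s2
        if t.Ginv is None:
            C[sl, sl] += lam * np.eye(q)
        else:
            C[sl, sl] += lam * t.Ginv
        off += q
    try:
        cho = scipy.linalg.cho_factor(C, lower=True)
        sol = scipy.linalg.cho_solve(cho, rhs)
    except scipy.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular MME coefficient matrix; check fixed-effect constraints")
    resid = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-30))

    beta = pd.Series(sol[:p], index=system.fixed_names)
    solutions = {t.name: pd.Series(sol[slices[t.name]], index=t.levels)
                 for t in system.terms}
    pev: dict[str, pd.Series] = {}
    if compute_pev:
        Cinv = scipy.linalg.cho_solve(cho, np.eye(C.shape[0]))
        d = np.diag(Cinv)
        for t in system.terms:
            if t.name in GENETIC_TERMS or t.gamma_diag is not None:
                pev[t.name] = pd.Series(d[slices[t.name]] * se2, index=t.levels)
    gdiag = {t.name: pd.Series(t.gamma_diag, index=t.levels)
             for t in system.terms if t.gamma_diag is not None}
    return MixedModelFit(beta=beta, solutions=solutions, pev=pev, vc=vc,
                         mme_residual=resid, gamma_diag=gdiag)


def _profile_matrices(system: MMESystem) -> tuple[list[np.ndarray], list[int]]:
    Ks, qs = [], []
    for t in system.terms:
        if t.Ginv is None:
            Ks.append(t.Z @ t.Z.T)
        else:
            G = _ginv(t.Ginv)  # invert back; terms store Ginv
            Ks.append(t.Z @ G @ t.Z.T)
        qs.append(t.n_levels)
    return Ks, qs


def reml_estimate(system: MMESystem, init: VarianceComponents | None = None,
                  method: str = "ai", tol: float = 1e-6, max_iter: int = 200
                  ) -> tuple[VarianceComponents, dict]:
    """REML variance components by EM or average-information iteration.

    The dense restricted likelihood is profiled through
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.  AI proposals that leave the
    parameter space fall back to an EM step for that iteration; iterates
    are floored at 1e-10 times the phenotypic variance (boundary zeros are
    reported as the floor).  Suited to the moderate problem sizes of
    simulation studies; not an out-of-core solver.
    """
    if method not in ("em", "ai"):
        raise ValueError("method must be 'em' or 'ai'")
    y, X = system.y, system.X
    n = len(y)
    vary = float(np.var(y, ddof=1))
    floor = 1e-10 * vary
    Ks, qs = _profile_matrices(system)
    names = [t.name for t in system.terms]
    if init is None:
        k = len(names) + 1
        theta = np.full(k, vary / k)
    else:
        theta = np.array([init.by_term[nm] for nm in names] + [init.residual])
        if (theta <= 0).any():
            raise ValueError("initial variance components must be positive")
    qs_all = qs + [n]
    info: dict = {"iterations": 0, "converged": False, "loglik_path": []}

    def quantities(th):
        V = th[-1] * np.eye(n)
        for s2, K in zip(th[:-1], Ks):
            V += s2 * K
        Vinv = _ginv(V)
        VX = Vinv @ X
        XtVX = X.T @ VX
        P = Vinv - VX @ np.linalg.solve(XtVX, VX.T)
        Py = P @ y
        sign, ld_v = np.linalg.slogdet(V)
        _, ld_x = np.linalg.slogdet(XtVX)
        ll = -0.5 * (ld_v + ld_x + float(y @ Py))
        return P, Py, ll

    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        P, Py, ll = quantities(theta)
        info["loglik_path"].append(ll)
        Kmats = Ks + [np.eye(n)]
        u = [K @ Py for K in Kmats]
        score = np.array([
            -0.5 * (float(np.sum(P * K)) - float(Py @ uk))
            for K, uk in zip(Kmats, u)])
        em = theta + theta**2 / np.array(qs_all) * np.array(
            [float(Py @ uk) - float(np.sum(P * K))
             for K, uk in zip(Kmats, u)])
        if method == "ai":
            Pu = [P @ uk for uk in u]
            AI = 0.5 * np.array([[float(ui @ Puj) for Puj in Pu] for ui in u])
            try:
                step = np.linalg.solve(AI + 1e-12 * np.eye(len(u)), score)
                cand = theta + step
                if (cand[:-1] < 0).any() or cand[-1] <= 0 or \
                        not np.isfinite(cand).all():
                    cand = em
            except np.linalg.LinAlgError:
                cand = em
        else:
            cand = em
        cand = np.maximum(cand, floor)
        rel = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), floor))
        theta = cand
        info["iterations"] = it
        # converged when parameters settle, or the restricted likelihood has
        # (components drifting to the boundary change forever in relative terms)
        if rel < tol or abs(ll - prev_ll) < 1e-9 * (1.0 + abs(ll)):
            info["converged"] = True
            break
        prev_ll = ll
    _, _, ll = quantities(theta)
    info["loglik"] = ll
    vc = VarianceComponents({nm: float(v) for nm, v in zip(names, theta[:-1])},
                            float(theta[-1]))
    return vc, info


def fit_model(phenotypes: pd.DataFrame, design: MatingDesign,
              gammas: GammaStructure, spec: ModelSpec | None = None,
              vc: VarianceComponents | None = None,
              reml_method: str = "ai", max_iter: int = 200) -> MixedModelFit:
    """Convenience wrapper: build design, estimate components, solve MME."""
    system = build_design(phenotypes, design, gammas, spec)
    if vc is None:
        vc, info = reml_estimate(system, method=reml_method, max_iter=max_iter)
        vc = _floor_vc(vc)
        fit = solve_mme(system, vc)
        fit.loglik = info.get("loglik")
        fit.converged = info.get("converged", False)
        return fit
    return solve_mme(system, vc)


def _floor_vc(vc: VarianceComponents, eps_frac: float = 1e-8) -> VarianceComponents:
    """Lift boundary-zero components slightly so the MME stays invertible."""
    base = max(vc.residual, max(vc.by_term.values(), default=0.0))
    eps = eps_frac * base if base > 0 else 1e-12
    return VarianceComponents({k: max(v, eps) for k, v in vc.by_term.items()},
                              max(vc.residual, eps))


def identity_gammas(design: MatingDesign) -> GammaStructure:
    """Gamma_A = Gamma_B = I over the design's parents (reference cross
    values: no shrinkage towards family means)."""
    pa, pb = design.parents_a, design.parents_b
    ga = RelationshipMatrix(pa, np.eye(len(pa)), "gamma_additive")
    gb = RelationshipMatrix(pb, np.eye(len(pb)), "gamma_additive")
    gd = dominance_gamma(ga, gb, design)
    return GammaStructure(ga, gb, gd)


def pedigree_gammas(design: MatingDesign, pedigree_a: Pedigree,
                    pedigree_b: Pedigree,
                    parents_a: list[str] | None = None,
                    parents_b: list[str] | None = None) -> GammaStructure:
    """Gamma = 0.5 A per group (genealogical coancestries), plus Gamma_D."""
    pa = parents_a if parents_a is not None else design.parents_a
    pb = parents_b if parents_b is not None else design.parents_b
    aa = pedigree_relationship(pedigree_a, pa)
    ab = pedigree_relationship(pedigree_b, pb)
    ga = RelationshipMatrix(pa, 0.5 * aa.values, "gamma_additive")
    gb = RelationshipMatrix(pb, 0.5 * ab.values, "gamma_additive")
    gd = dominance_gamma(ga, gb, design)
    return GammaStructure(ga, gb, gd)


def reference_values(phenotypes: pd.DataFrame, design: MatingDesign,
                     pedigree_a: Pedigree | None = None,
                     pedigree_b: Pedigree | None = None,
                     mode: str = "cross_values",
                     spec: ModelSpec | None = None,
                     vc: VarianceComponents | None = None
                     ) -> tuple[CrossValuePrediction, pd.Series, pd.Series, MixedModelFit]:
    """Reference cross values / parental GCAs from one site's phenotypes.

    mode="cross_values": identity Gammas, so GCAs are not shrunk towards
    family means and the three-term sum tracks the design-adjusted cross
    mean.  mode="parental_gcas": Gamma = 0.5 A from the pedigrees, the
    pre-genomic evaluation.
    """
    if mode == "cross_values":
        gammas = identity_gammas(design)
    elif mode == "parental_gcas":
        if pedigree_a is None or pedigree_b is None:
            raise ValueError("pedigrees required for parental_gcas mode")
        gammas = pedigree_gammas(design, pedigree_a, pedigree_b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    fit = fit_model(phenotypes, design, gammas, spec, vc=vc)
    pred = fit.cross_values(design, with_sca=True)
    return pred, fit.solutions["gA"], fit.solutions["gB"], fit


def genomic_predict(train_phenotypes: pd.DataFrame, design: MatingDesign,
                    gammas: GammaStructure, spec: ModelSpec | None = None,
                    with_sca: bool = True,
                    vc: VarianceComponents | None = None
                    ) -> tuple[CrossValuePrediction, pd.Series, pd.Series, MixedModelFit]:
    """Predict unphenotyped validation crosses/parents through the Gammas.

    ``design`` must list every cross (training and validation) and the
    Gamma matrices every parent; phenotypes cover the training crosses
    only.  BLUPs of validation levels arise from their covariance with the
    trained levels (GBLUP when the Gammas are marker-derived, PBLUP when
    they are pedigree-derived).
    """
    for c, (a, b) in design.parent_map().items():
        if a not in set(gammas.gamma_a.ids):
            raise KeyError(f"parent {a!r} missing from gamma_A")
        if b not in set(gammas.gamma_b.ids):
            raise KeyError(f"parent {b!r} missing from gamma_B")
    fit = fit_model(train_phenotypes, design, gammas, spec, vc=vc)
    pred = fit.cross_values(design, with_sca=with_sca)
    return pred, fit.solutions["gA"], fit.solutions["gB"], fit


def dominance_proportion(vc: VarianceComponents, gammas: GammaStructure) -> float:
    """Share of dominance (SCA) variance in total between-cross genetic
    variance: (Tr(GD)/nD) s2_d / ((Tr(GD)/nD) s2_d + (Tr(GA)/nA) s2_gA +
    (Tr(GB)/nB) s2_gB)."""
    s2a = vc.by_term.get("gA", 0.0)
    s2b = vc.by_term.get("gB", 0.0)
    s2d = vc.by_term.get("sAB", 0.0)
    ta = np.trace(gammas.gamma_a.values) / len(gammas.gamma_a.ids)
    tb = np.trace(gammas.gamma_b.values) / len(gammas.gamma_b.ids)
    if gammas.gamma_d is None:
        raise ValueError("gamma_d required")
    td = np.trace(gammas.gamma_d.values) / len(gammas.gamma_d.ids)
    denom = td * s2d + ta * s2a + tb * s2b
    if denom == 0:
        raise ValueError("all genetic variances are zero")
    return float(td * s2d / denom)


def accuracy_from_pev(pev: float, gamma_ii: float, sigma2: float) -> float:
    """Individual selection accuracy sqrt(1 - PEV / (Gamma_ii sigma^2))."""
    bound = gamma_ii * sigma2
    if not 0.0 <= pev <= bound * (1 + 1e-9):
        raise ValueError(f"PEV {pev} outside [0, {bound}]")
    return float(np.sqrt(max(0.0, 1.0 - pev / bound)))


def mean_accuracy(fit: MixedModelFit, term: str, ids: list[str] | None = None) -> float:
    """Mean PEV-based selection accuracy over the levels of a genetic term."""
    t_pev = fit.pev[term]
    sigma2 = fit.vc.by_term[term]
    gdiag = fit.gamma_diag.get(term, pd.Series(1.0, index=t_pev.index))
    use = list(t_pev.index) if ids is None else [i for i in t_pev.index if i in set(ids)]
    accs = []
    for lev in use:
        bound = gdiag[lev] * sigma2
        accs.append(accuracy_from_pev(min(t_pev[lev], bound), gdiag[lev], sigma2))
    return float(np.mean(accs))
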