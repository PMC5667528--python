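"""Relationship matrices for the hybrid GCA/SCA mixed models.

Five constructions are provided:

* pedigree numerator relationship A (tabular method), elements 2*f_xy where
  f_xy is the coefficient of coancestry;
* molecular coancestry (allele-sharing similarity index);
* VanRaden genomic relationship G from centred dosages;
* the combined pedigree-genomic matrix Gamma, assembled on the inverse scale
  as Gamma^-1 = (0.5 A)^-1 + [0 0; 0 G^-1 - (0.5 A_22)^-1], which extends
  marker information to non-genotyped relatives (single-step construction);
* the cross-level dominance matrix Gamma_D with elements
  Gamma_A(a,a') * Gamma_B(b,b'), the coefficients of fraternity between
  crosses sharing parents (the two parental groups are unrelated, so the
  Kronecker-product structure restricted to observed crosses applies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeTable, MatingDesign, Pedigree, RelationshipMatrix


def pedigree_relationship(pedigree: Pedigree,
                          subjects: list[str] | None = None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Diagonal elements are 1 + F (F the inbreeding coefficient); off-diagonals
    2*f_xy.  ``subjects`` selects (and orders) the rows/columns returned; all
    pedigree ancestors still contribute to the recursion.
    """
    ids = pedigree.ids
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = pedigree.records["sire"].to_numpy()
    dams = pedigree.records["dam"].to_numpy()
    for i in range(n):
        s = pos.get(sires[i], -1)
        d = pos.get(dams[i], -1)
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    out = RelationshipMatrix(ids, A, "pedigree_A")
    if subjects is not None:
        missing = [s for s in subjects if s not in pos]
        if missing:
            raise KeyError(f"subjects not in pedigree: {missing[:4]}")
        out = RelationshipMatrix(list(subjects), out.loc(list(subjects)), "pedigree_A")
    return out


def molecular_coancestry(genotypes: GenotypeTable) -> RelationshipMatrix:
    """Allele-sharing similarity between all pairs of genotyped individuals.

    At each locus the similarity is the mean of the four allele-identity
    indicators between the two genotypes: identical homozygotes score 1,
    opposite homozygotes 0, and any pair involving a heterozygote 0.5.
    Scores are averaged over the loci where both calls are non-missing; a
    pair sharing no called locus gets NaN.
    """
    D = genotypes.dosage
    obs = ~np.isnan(D)
    Df = np.nan_to_num(D)
    het = (Df == 1.0) & obs

    # s = 1 - |d1-d2|/2, overridden to 0.5 when both are heterozygous.
    # Accumulate pairwise sums with matrix products to stay O(n^2 m).
    n = genotypes.n_individuals
    S = np.zeros((n, n))
    shared = obs.astype(float) @ obs.T.astype(float)
    # sum over shared loci of |d1-d2|: expand |d1-d2| via products of
    # indicator columns for dosage 0/1/2
    ind = [((Df == k) & obs).astype(float) for k in (0.0, 1.0, 2.0)]
    absdiff = np.zeros((n, n))
    for a in range(3):
        for b in range(3):
            if a != b:
                absdiff += abs(a - b) * (ind[a] @ ind[b].T)
    S = shared - absdiff / 2.0
    # both-het correction: counted as 1 above, should be 0.5
    both_het = ind[1] @ ind[1].T
    S -= 0.5 * both_het
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(shared > 0, S / shared, np.nan)
    out = (out + out.T) / 2.0
    return RelationshipMatrix(genotypes.ids, out, "molecular_f")


def vanraden_G(genotypes: GenotypeTable,
               freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """Genomic relationship matrix G = W W' / (2 sum p_k (1-p_k)).

    W is the dosage matrix centred by twice the alternate-allele frequency.
    Frequencies default to those observed in the table (the within-group
    convention: build G separately per parental group).  Requires complete,
    polymorphic dosages — run imputation and QC first.
    """
    D = genotypes.dosage
    if np.isnan(D).any():
        raise ValueError("missing dosages present; impute before building G")
    p = np.asarray(freqs, dtype=float) if freqs is not None else D.mean(axis=0) / 2.0
    if p.shape != (genotypes.n_snps,):
        raise ValueError("frequency vector length mismatch")
    mono = (p <= 0) | (p >= 1) | (D.std(axis=0) == 0)
    if mono.any():
        k = int(np.flatnonzero(mono)[0])
        raise ValueError(
            f"monomorphic SNP at column {k} ({genotypes.snps['snp_id'].iloc[k]}); filter first")
    W = D - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (W @ W.T) / denom
    return RelationshipMatrix(genotypes.ids, G, "genomic_G")


@dataclass
class CombinedGamma:
    """Combined pedigree-genomic Gamma on both scales, with its id order.

    ``ids`` lists non-genotyped individuals first, then genotyped ones, in a
    stable order derived from the pedigree A matrix.
    """

    gamma_inverse: RelationshipMatrix
    gamma: RelationshipMatrix
    genotyped_ids: list[str]
    blend_weight: float


def condition_G(G: np.ndarray, half_A22: np.ndarray, weight: float = 0.99) -> np.ndarray:
    """Blend G towards the pedigree expectation for invertibility.

    G* = w G + (1-w) (0.5 A_22); w = 1 leaves G untouched.
    """
    if not (0.0 < weight <= 1.0):
        raise ValueError("blend weight must be in (0, 1]")
    return weight * G + (1.0 - weight) * half_A22


def combined_gamma_inverse(A: RelationshipMatrix, G: RelationshipMatrix | None,
                           genotyped_ids: list[str],
                           blend_weight: float = 0.99) -> CombinedGamma:
    """Assemble Gamma^-1 = (0.5A)^-1 + [0 0; 0 G*^-1 - (0.5 A_22)^-1].

    With no genotyped individuals this is Gamma = 0.5 A; with every
    individual genotyped it reduces to Gamma = G*.  The returned ids order
    non-genotyped before genotyped individuals.
    """
    genotyped_ids = [str(i) for i in genotyped_ids]
    aset = set(A.ids)
    missing = [i for i in genotyped_ids if i not in aset]
    if missing:
        raise KeyError(f"genotyped ids absent from A: {missing[:4]}")
    non_gen = [i for i in A.ids if i not in set(genotyped_ids)]
    order = non_gen + genotyped_ids
    halfA = 0.5 * A.loc(order)
    n1 = len(non_gen)
    if genotyped_ids:
        if G is None:
            raise ValueError("G required when genotyped_ids is non-empty")
        if set(G.ids) != set(genotyped_ids):
            raise ValueError("G must cover exactly the genotyped ids")
        G22 = G.loc(genotyped_ids)
        halfA22 = halfA[n1:, n1:]
        Gstar = condition_G(G22, halfA22, blend_weight)
        Gstar_inv = _inv_psd(Gstar, "conditioned G")
        halfA22_inv = _inv_psd(halfA22, "0.5*A22")
    halfA_inv = _inv_psd(halfA, "0.5*A")
    Ginv_full = halfA_inv.copy()
    if genotyped_ids:
        Ginv_full[n1:, n1:] += Gstar_inv - halfA22_inv
    gamma = _inv_psd(Ginv_full, "Gamma inverse")
    return CombinedGamma(
        gamma_inverse=RelationshipMatrix(order, Ginv_full, "gamma_inverse"),
        gamma=RelationshipMatrix(order, gamma, "gamma_additive"),
        genotyped_ids=genotyped_ids,
        blend_weight=blend_weight,
    )


def _inv_psd(M: np.ndarray, label: str) -> np.ndarray:
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(f"{label} block is not positive definite") from None
    Linv = np.linalg.inv(L)
    return Linv.T @ Linv


def dominance_gamma(gamma_a: RelationshipMatrix, gamma_b: RelationshipMatrix,
                    crosses: MatingDesign) -> RelationshipMatrix:
    """Cross-level dominance covariance over the observed crosses only.

    Element for crosses (a x b, a' x b') is Gamma_A(a,a') * Gamma_B(b,b');
    the full Kronecker product is never materialised when the factorial is
    incomplete.
    """
    pm = crosses.parent_map()
    apos = {i: k for k, i in enumerate(gamma_a.ids)}
    bpos = {i: k for k, i in enumerate(gamma_b.ids)}
    cross_ids = crosses.cross_ids
    for cid in cross_ids:
        a, b = pm[cid]
        if a not in apos:
            raise KeyError(f"A parent {a!r} of cross {cid!r} missing from gamma_A")
        if b not in bpos:
            raise KeyError(f"B parent {b!r} of cross {cid!r} missing from gamma_B")
    ai = np.array([apos[pm[c][0]] for c in cross_ids])
    bi = np.array([bpos[pm[c][1]] for c in cross_ids])
    GD = gamma_a.values[np.ix_(ai, ai)] * gamma_b.values[np.ix_(bi, bi)]
    return RelationshipMatrix(cross_ids, GD, "gamma_dominance")


@dataclass
class CoancestrySummary:
    """Max coancestry of each validation individual with the training set."""

    per_validation: pd.Series  # index: validation id, value: f_max
    mean: float
    min: float
    max: float


def coancestry_summary(matrix: RelationshipMatrix, validation_ids: list[str],
                       training_ids: list[str]) -> CoancestrySummary:
    """f_max V-T: per validation individual, its maximum coancestry with any
    training individual, summarised over the validation set.

    For a pedigree numerator matrix the coancestry is half the relationship
    element; molecular similarity matrices are used as-is.
    """
    if not training_ids:
        raise ValueError("empty training set")
    vals = matrix.loc(list(validation_ids), list(training_ids))
    scale = 0.5 if matrix.kind == "pedigree_A" else 1.0
    fmax = np.nanmax(vals, axis=1) * scale
    per = pd.Series(fmax, index=list(validation_ids), name="f_max")
    return CoancestrySummary(per, float(per.mean()), float(per.min()), float(per.max()))


def write_matrix(matrix: RelationshipMatrix, path) -> None:
    """Dense delimited text with an id header row and column."""
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, sep="\t", index_label=matrix.kind)


def read_matrix(path, kind: str | None = None) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    k = kind or str(df.index.name or "gamma_additive")
    return RelationshipMatrix([str(i) for i in df.index], df.to_numpy(float), k)
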