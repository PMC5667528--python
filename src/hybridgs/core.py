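"""Core data containers shared across the package.

The package models two-group (A x B) hybrid breeding data: multi-generation
pedigrees within each heterotic group, biallelic SNP genotypes of the parents
with per-call sequencing depth (GBS-style), an incomplete-factorial mating
design between the groups, and phenotype records on the hybrid individuals.

All cross-module joins are by id, never by position; every matrix carries an
explicit ordered id list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

#: canonical phenotype-table columns
PHENOTYPE_COLUMNS = [
    "cross", "trial", "block", "incomplete_block", "plot",
    "individual", "age", "trait", "value",
]


@dataclass
class Pedigree:
    """Directed acyclic parentage over named individuals of the two groups.

    ``records`` has columns id, sire, dam, group, generation; the string "0"
    denotes an unknown parent.  Records are stored parent-before-offspring.
    """

    records: pd.DataFrame

    REQUIRED = ["id", "sire", "dam", "group", "generation"]

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=self.REQUIRED).copy()
        for c in ("id", "sire", "dam", "group"):
            df[c] = df[c].astype(str)
        df["generation"] = df["generation"].astype(int)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicated individual id {dup!r} in pedigree")
        known = set(df["id"])
        for col in ("sire", "dam"):
            bad = df.loc[(df[col] != UNKNOWN_PARENT) & ~df[col].isin(known), col]
            if len(bad):
                raise ValueError(f"unknown {col} id {bad.iloc[0]!r} in pedigree")
        df = _toposort(df)
        self.records = df.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return list(self.records["id"])

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        row = self.records.loc[self.records["id"] == individual]
        if row.empty:
            raise KeyError(individual)
        s, d = row.iloc[0]["sire"], row.iloc[0]["dam"]
        return (None if s == UNKNOWN_PARENT else s,
                None if d == UNKNOWN_PARENT else d)

    def group_ids(self, group: str) -> list[str]:
        return list(self.records.loc[self.records["group"] == group, "id"])


def _toposort(df: pd.DataFrame) -> pd.DataFrame:
    """Order records parent-before-offspring; raise on cycles."""
    pos = {i: k for k, i in enumerate(df["id"])}
    children: dict[str, list[str]] = {i: [] for i in df["id"]}
    indeg = {i: 0 for i in df["id"]}
    for _, r in df.iterrows():
        for p in (r["sire"], r["dam"]):
            if p != UNKNOWN_PARENT:
                children[p].append(r["id"])
                indeg[r["id"]] += 1
    # selfing contributes 2 to in-degree via the same parent; dedupe edges
    order: list[str] = []
    ready = sorted([i for i, d in indeg.items() if d == 0], key=pos.get)
    while ready:
        i = ready.pop(0)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
        ready.sort(key=pos.get)
    if len(order) != len(df):
        stuck = [i for i, d in indeg.items() if d > 0]
        raise ValueError(f"pedigree contains a cycle involving {stuck[:4]}")
    return df.set_index("id").loc[order].reset_index()


@dataclass
class GenotypeTable:
    """Individuals x biallelic SNPs with dosage, per-call depth, missing mask.

    dosage: float array, values {0, 1, 2} or NaN (missing).
    depth:  float array, non-negative read counts; NaN = depth unknown
            (e.g. VCF without DP), which is exempt from depth masking.
    snps:   DataFrame with snp_id, chrom, pos (1-based), ref, alt.
    groups: per-individual group label aligned with ``ids`` (optional).
    """

    ids: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.ids) != n or len(self.snps) != m:
            raise ValueError("dosage shape does not match ids/snps")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be 0/1/2 or NaN")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
            if self.depth.shape != self.dosage.shape:
                raise ValueError("depth shape mismatch")
            if np.nanmin(self.depth, initial=0) < 0:
                raise ValueError("negative depth")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
            if len(self.groups) != n:
                raise ValueError("groups length mismatch")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def index_of(self, individuals: list[str]) -> np.ndarray:
        pos = {i: k for k, i in enumerate(self.ids)}
        try:
            return np.array([pos[i] for i in individuals], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"individual {e.args[0]!r} not genotyped") from None

    def subset(self, individuals: list[str] | None = None,
               snp_ids: list[str] | None = None) -> "GenotypeTable":
        rows = (self.index_of(individuals) if individuals is not None
                else np.arange(self.n_individuals))
        if snp_ids is not None:
            spos = {s: k for k, s in enumerate(self.snps["snp_id"])}
            cols = np.array([spos[s] for s in snp_ids], dtype=int)
        else:
            cols = np.arange(self.n_snps)
        return GenotypeTable(
            ids=[self.ids[r] for r in rows],
            snps=self.snps.iloc[cols].reset_index(drop=True),
            dosage=self.dosage[np.ix_(rows, cols)].copy(),
            depth=None if self.depth is None else self.depth[np.ix_(rows, cols)].copy(),
            groups=None if self.groups is None else self.groups[rows].copy(),
        )


@dataclass
class MatingDesign:
    """Incomplete-factorial A x B mating design: one A and one B parent per cross."""

    crosses: pd.DataFrame  # columns cross, parent_a, parent_b

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.crosses, columns=["cross", "parent_a", "parent_b"]).copy()
        for c in df.columns:
            df[c] = df[c].astype(str)
        if df["cross"].duplicated().any():
            raise ValueError("duplicated cross id in mating design")
        self.crosses = df.reset_index(drop=True)

    @property
    def cross_ids(self) -> list[str]:
        return list(self.crosses["cross"])

    @property
    def parents_a(self) -> list[str]:
        return sorted(self.crosses["parent_a"].unique())

    @property
    def parents_b(self) -> list[str]:
        return sorted(self.crosses["parent_b"].unique())

    def parent_map(self) -> dict[str, tuple[str, str]]:
        return {r.cross: (r.parent_a, r.parent_b)
                for r in self.crosses.itertuples(index=False)}


@dataclass
class RelationshipMatrix:
    """A symmetric covariance-defining matrix with its ordered subject ids.

    kind is one of pedigree_A, molecular_f, genomic_G, gamma_additive,
    gamma_dominance, gamma_inverse.
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "gamma_additive"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-8, equal_nan=True):
            raise ValueError("matrix is not symmetric")

    def loc(self, rows: list[str], cols: list[str] | None = None) -> np.ndarray:
        pos = {i: k for k, i in enumerate(self.ids)}
        ri = [pos[i] for i in rows]
        ci = ri if cols is None else [pos[i] for i in cols]
        return self.values[np.ix_(ri, ci)]

    def reorder(self, ids: list[str]) -> "RelationshipMatrix":
        return RelationshipMatrix(ids, self.loc(list(ids)), self.kind)


@dataclass
class GammaStructure:
    """The three covariance-defining matrices of the hybrid mixed model.

    gamma_a / gamma_b define the covariance among GCAs within each parental
    group; gamma_d the covariance among SCAs of the observed crosses.
    """

    gamma_a: RelationshipMatrix
    gamma_b: RelationshipMatrix
    gamma_d: RelationshipMatrix | None = None


def validate_phenotypes(df: pd.DataFrame,
                        production_age_range: tuple[int, int] = (3, 7)) -> pd.DataFrame:
    """Validate and normalise a phenotype table to the canonical columns."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    out = df[PHENOTYPE_COLUMNS].copy()
    if not np.isfinite(out["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite phenotype value")
    ages = out["age"].dropna()
    if len(ages):
        lo, hi = production_age_range
        a = ages.astype(float)
        if (a < lo).any() or (a > hi).any():
            raise ValueError(f"age outside the production range {lo}-{hi}")
    return out
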