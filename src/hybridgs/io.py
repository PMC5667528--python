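"""File formats: VCF genotypes, 3-column pedigrees, CSV phenotypes.

Coordinates are 1-based as in VCF; dosage is the alternate-allele count
from GT and depth comes from the per-sample DP field (absent DP = depth
unknown, which the QC depth mask leaves alone).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import GenotypeTable, Pedigree, PHENOTYPE_COLUMNS, UNKNOWN_PARENT, validate_phenotypes


def write_vcf(genotypes: GenotypeTable, path) -> None:
    """Plain-text VCF 4.2 with GT and per-call DP."""
    snps = genotypes.snps
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.ids) + "\n")
        gt_str = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        D = genotypes.dosage
        depth = genotypes.depth
        for j in range(genotypes.n_snps):
            row = snps.iloc[j]
            fields = [str(row["chrom"]), str(int(row["pos"])), str(row["snp_id"]),
                      str(row.get("ref", "A")), str(row.get("alt", "T")),
                      ".", "PASS", ".", "GT:DP"]
            for i in range(genotypes.n_individuals):
                g = "./." if np.isnan(D[i, j]) else gt_str[D[i, j]]
                if depth is None or np.isnan(depth[i, j]):
                    d = "."
                else:
                    d = str(int(depth[i, j]))
                fields.append(f"{g}:{d}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path, groups: dict[str, str] | None = None) -> GenotypeTable:
    """Parse a VCF into a GenotypeTable (GT required, DP optional)."""
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snp_rows, dosage_rows, depth_rows = [], [], []
    has_dp_format = any(h.type == "FORMAT" and h.info().get("ID") == "DP"
                        for h in vcf.header_iter())
    for var in vcf:
        alts = var.ALT or []
        alt = alts[0] if len(alts) == 1 else ",".join(alts) if alts else "."
        snp_rows.append({
            "snp_id": var.ID or f"{var.CHROM}_{var.POS}",
            "chrom": var.CHROM, "pos": var.POS,
            "ref": var.REF, "alt": alt,
        })
        gts = var.genotype.array()
        a = gts[:, :-1].astype(float)
        a[a < 0] = np.nan
        dose = a.sum(axis=1)
        # multi-allelic dosages are not 0/1/2; mark missing (QC drops the site)
        bad = ~np.isin(dose, (0.0, 1.0, 2.0)) & ~np.isnan(dose)
        dose[bad | np.isnan(a).any(axis=1)] = np.nan
        dosage_rows.append(dose)
        if has_dp_format:
            dp = var.format("DP")
            if dp is None:
                depth_rows.append(np.full(len(ids), np.nan))
            else:
                dpv = dp.astype(float).reshape(len(ids))
                dpv[dpv < 0] = np.nan
                depth_rows.append(dpv)
    snps = pd.DataFrame(snp_rows)
    dosage = np.vstack(dosage_rows).T if dosage_rows else np.empty((len(ids), 0))
    depth = np.vstack(depth_rows).T if depth_rows and has_dp_format else None
    garr = (np.array([groups.get(i, "all") for i in ids], dtype=object)
            if groups else None)
    return GenotypeTable(ids=ids, snps=snps, dosage=dosage, depth=depth,
                         groups=garr)


def write_pedigree(pedigree: Pedigree, path, full: bool = False) -> None:
    """Whitespace-delimited pedigree: id sire dam [group generation]."""
    cols = ["id", "sire", "dam"] + (["group", "generation"] if full else [])
    pedigree.records[cols].to_csv(path, sep=" ", index=False, header=full)


def read_pedigree(path, group: str = "all") -> Pedigree:
    """Read a 3-column (id sire dam) or 5-column pedigree file.

    "0" denotes an unknown parent.  Without group/generation columns the
    generation index is the topological depth and all records get
    ``group``.  Records may appear in any topologically valid order;
    cycles are rejected.
    """
    first = pd.read_csv(path, sep=r"\s+", nrows=1, header=None, dtype=str)
    if set(first.iloc[0]) >= {"id", "sire", "dam"}:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    else:
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
        if len(df.columns) == 3:
            df.columns = ["id", "sire", "dam"]
        elif len(df.columns) == 5:
            df.columns = ["id", "sire", "dam", "group", "generation"]
        else:
            raise ValueError("pedigree file must have 3 or 5 columns")
    if "group" not in df.columns:
        df["group"] = group
    if "generation" not in df.columns:
        depth: dict[str, int] = {}
        parents = {r["id"]: (r["sire"], r["dam"]) for _, r in df.iterrows()}

        def dep(i, seen=()):
            if i in depth:
                return depth[i]
            if i in seen:
                raise ValueError(f"pedigree cycle involving {i!r}")
            s, d = parents.get(i, (UNKNOWN_PARENT, UNKNOWN_PARENT))
            val = 0
            for p in (s, d):
                if p != UNKNOWN_PARENT and p in parents:
                    val = max(val, dep(p, seen + (i,)) + 1)
            depth[i] = val
            return val

        df["generation"] = [dep(i) for i in df["id"]]
    return Pedigree(df[["id", "sire", "dam", "group", "generation"]])


def write_phenotypes(df: pd.DataFrame, path) -> None:
    validate_phenotypes(df).to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_phenotypes(df)
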