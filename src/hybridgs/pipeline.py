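"""End-to-end orchestration: simulate -> qc -> relmat -> fit -> evaluate ->
preselect, each stage reading the previous stage's on-disk artifacts.

Configuration is a plain-text key-value file with ``section.key = value``
lines; a single root seed derives a named substream per stage.  Every stage
writes its outputs under the run directory and appends per-stage counts to
``run.log``; a ``manifest.json`` stamps the config hash and seed.  Stages
never mutate another stage's artifacts, so single-stage reruns with
unchanged inputs are idempotent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .core import MatingDesign
from .evaluate import accuracy, split_validation
from .mixedmodel import ModelSpec, genomic_predict, reference_values
from .evaluate import build_genomic_gammas
from .preselect import (GroupSimParams, SchemeConfig, economic_conversion,
                        simulate_schemes)
from .qc import FilterConfig, apply_site_filters, mendelian_filter
from .relmat import write_matrix
from .simulate import (PopulationSpec, SimVarianceComponents, TrialLayout,
                       simulate_breeding_population, simulate_mating_design,
                       simulate_phenotypes)

STAGES = ("simulate", "qc", "relmat", "fit", "evaluate", "preselect")


@dataclass
class PipelineConfig:
    out_dir: Path
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    params: dict[str, dict[str, str]] = field(default_factory=dict)

    def get(self, section: str, key: str, default=None, cast=str):
        v = self.params.get(section, {}).get(key)
        return default if v is None else cast(v)


def load_config(path, out_dir=None) -> PipelineConfig:
    """Parse a ``section.key = value`` plain-text configuration file."""
    params: dict[str, dict[str, str]] = {}
    stages = STAGES
    seed = 0
    out = out_dir
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "stages":
            stages = tuple(s.strip() for s in val.split(",") if s.strip())
        elif key == "seed":
            seed = int(val)
        elif key == "out_dir" and out is None:
            out = val
        elif "." in key:
            sec, k = key.split(".", 1)
            params.setdefault(sec, {})[k] = val
    if out is None:
        raise ValueError("configuration must set out_dir")
    return PipelineConfig(Path(out), stages, seed, params)


def _substream(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the toggled stages, returning the artifact paths produced."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = out / "run.log"
    artifacts: dict[str, Path] = {}
    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "config_hash": hashlib.sha256(
            json.dumps(config.params, sort_keys=True).encode()).hexdigest()[:16],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def logline(msg: str) -> None:
        with open(log, "a") as fh:
            fh.write(msg + "\n")

    def need(name: str, stage: str) -> Path:
        p = out / name
        if not p.exists():
            raise FileNotFoundError(
                f"stage {stage!r} requires missing artifact {p.name!r}; "
                "run its producing stage first")
        return p

    if "simulate" in config.stages:
        seed = _substream(config.seed, "simulate")
        g = config.get
        tabs, peds = {}, {}
        for k, label in enumerate("AB"):
            spec = PopulationSpec(
                group_label=label,
                n_founders=g("simulate", "n_founders", 4, int),
                n_generations=g("simulate", "n_generations", 2, int),
                n_individuals_per_generation=g("simulate", "per_generation", 20, int),
                n_snps=g("simulate", "n_snps", 300, int),
                seed=seed + k)
            peds[label], tabs[label] = simulate_breeding_population(spec)
        merged = merge_tables(tabs["A"], tabs["B"])
        parents_a = peds["A"].group_ids("A")[-g("simulate", "n_parents", 15, int):]
        parents_b = peds["B"].group_ids("B")[-g("simulate", "n_parents", 15, int):]
        design = simulate_mating_design(
            parents_a, parents_b,
            g("simulate", "crosses_per_parent", 4, int), seed=seed)
        comp = SimVarianceComponents()
        layout = TrialLayout(n_trials=g("simulate", "n_trials", 1, int),
                             n_blocks=g("simulate", "n_blocks", 3, int),
                             palms_per_plot=g("simulate", "palms_per_plot", 3, int))
        phen, truth = simulate_phenotypes(design, peds["A"], peds["B"], merged,
                                          comp, layout, seed=seed)
        hio.write_vcf(tabs["A"], out / "genotypes_a.vcf")
        hio.write_vcf(tabs["B"], out / "genotypes_b.vcf")
        hio.write_pedigree(peds["A"], out / "pedigree_a.txt", full=True)
        hio.write_pedigree(peds["B"], out / "pedigree_b.txt", full=True)
        hio.write_phenotypes(phen, out / "phenotypes.csv")
        design.crosses.to_csv(out / "design.csv", index=False)
        truth.cross_values(design).rename_axis("cross").to_csv(out / "true_values.csv")
        logline(f"simulate: {merged.n_individuals} individuals, "
                f"{merged.n_snps} SNPs, {len(design.cross_ids)} crosses, "
                f"{len(phen)} phenotype records")
        artifacts.update({k: out / v for k, v in {
            "genotypes_a": "genotypes_a.vcf", "genotypes_b": "genotypes_b.vcf",
            "phenotypes": "phenotypes.csv", "design": "design.csv"}.items()})

    if "qc" in config.stages:
        # the molecular dataset is handled per parental group throughout
        fc = FilterConfig()
        for label in ("a", "b"):
            gt = hio.read_vcf(need(f"genotypes_{label}.vcf", "qc"))
            ped = hio.read_pedigree(need(f"pedigree_{label}.txt", "qc"))
            gt.groups = np.array([label.upper()] * gt.n_individuals, dtype=object)
            gt1, rep1 = apply_site_filters(gt, fc)
            gt2, rep2 = mendelian_filter(gt1, ped, fc)
            hio.write_vcf(gt2, out / f"qc_genotypes_{label}.vcf")
            pd.concat([rep1.to_frame(), rep2.to_frame()],
                      keys=["site_filters", "mendelian"]).to_csv(
                out / f"qc_report_{label}.tsv", sep="\t")
            logline(f"qc[{label.upper()}]: {rep1.input_sites} -> "
                    f"{rep1.retained_sites} -> {rep2.retained_sites} sites")
            artifacts[f"qc_genotypes_{label}"] = out / f"qc_genotypes_{label}.vcf"

    if "relmat" in config.stages or "fit" in config.stages:
        peda = hio.read_pedigree(need("pedigree_a.txt", "relmat"))
        pedb = hio.read_pedigree(need("pedigree_b.txt", "relmat"))
        design = MatingDesign(pd.read_csv(need("design.csv", "relmat"), dtype=str))
        gta = hio.read_vcf(need("qc_genotypes_a.vcf", "relmat"))
        gtb = hio.read_vcf(need("qc_genotypes_b.vcf", "relmat"))
        gta.groups = np.array(["A"] * gta.n_individuals, dtype=object)
        gtb.groups = np.array(["B"] * gtb.n_individuals, dtype=object)
        gt = merge_tables(gta, gtb)
        gammas = build_genomic_gammas(gt, design, peda, pedb)
        if "relmat" in config.stages:
            write_matrix(gammas.gamma_a, out / "gamma_a.tsv")
            write_matrix(gammas.gamma_b, out / "gamma_b.tsv")
            write_matrix(gammas.gamma_d, out / "gamma_d.tsv")
            logline(f"relmat: gamma_A {len(gammas.gamma_a.ids)}, "
                    f"gamma_B {len(gammas.gamma_b.ids)}, "
                    f"gamma_D {len(gammas.gamma_d.ids)}")
            artifacts["gamma_a"] = out / "gamma_a.tsv"

    if "fit" in config.stages:
        phen = hio.read_phenotypes(need("phenotypes.csv", "fit"))
        rng = np.random.default_rng(_substream(config.seed, "fit"))
        crosses = design.cross_ids
        n_val = max(3, len(crosses) // 3)
        val = list(rng.choice(crosses, n_val, replace=False))
        train = [c for c in crosses if c not in set(val)]
        phen_val = phen[phen["cross"].isin(val)]
        phen_train = phen[phen["cross"].isin(train)]
        val_design = MatingDesign(design.crosses[design.crosses["cross"].isin(val)])
        ref, _, _, rfit = reference_values(phen_val, val_design, mode="cross_values")
        pred, _, _, gfit = genomic_predict(phen_train, design, gammas,
                                           with_sca=False)
        ref.values.rename("reference").rename_axis("cross").to_csv(
            out / "reference_values.csv")
        pred.values.rename("predicted").rename_axis("cross").to_csv(
            out / "predictions.csv")
        pd.Series({**gfit.vc.by_term, "residual": gfit.vc.residual},
                  name="variance").rename_axis("component").to_csv(
            out / "variance_components.tsv", sep="\t")
        logline(f"fit: {len(train)} training / {len(val)} validation crosses; "
                f"REML converged={gfit.converged}")
        artifacts["predictions"] = out / "predictions.csv"

    if "evaluate" in config.stages:
        ref = pd.read_csv(need("reference_values.csv", "evaluate"),
                          index_col=0)["reference"]
        pred = pd.read_csv(need("predictions.csv", "evaluate"),
                           index_col=0)["predicted"]
        if len(ref) >= 9:  # sets need >= 3 crosses for a correlation
            k = min(3, len(ref) // 3)
            sets = split_validation(list(ref.index), k,
                                    seed=_substream(config.seed, "evaluate"))
        else:
            sets = [list(ref.index)]
        rows = [{"set": s, "n": len(m),
                 "accuracy": accuracy(ref[m], pred[pred.index.intersection(m)])}
                for s, m in enumerate(sets)]
        k = len(sets)
        pd.DataFrame(rows).to_csv(out / "accuracy.csv", index=False)
        logline(f"evaluate: {k} validation sets")
        artifacts["accuracy"] = out / "accuracy.csv"

    if "preselect" in config.stages:
        g = config.get
        pa = GroupSimParams("A", g("preselect", "var_a", 21.6, float),
                            g("preselect", "rpt_a", 0.54, float),
                            g("preselect", "rgs_a", 0.30, float))
        pb = GroupSimParams("B", g("preselect", "var_b", 56.4, float),
                            g("preselect", "rpt_b", 0.76, float),
                            g("preselect", "rgs_b", 0.77, float))
        cfg = SchemeConfig(
            n_candidates_a=g("preselect", "n_candidates_a", 1000, int),
            n_candidates_b=g("preselect", "n_candidates_b", 1000, int),
            n_replicates=g("preselect", "n_replicates", 2000, int),
            mu=g("preselect", "mu", 120.9, float),
            seed=_substream(config.seed, "preselect"))
        sim = simulate_schemes(pa, pb, cfg)
        econ = economic_conversion(max(sim.extra_kg, 1e-9))
        pd.DataFrame([{
            "mu_rrs": sim.mu_rrs, "mu_gp": sim.mu_gp,
            "percent_gain": sim.percent_gain, "extra_kg": sim.extra_kg,
            "ffb_t_ha_yr": econ.ffb_t_per_ha_year,
            "oil_kg_ha_yr": econ.oil_kg_per_ha_year,
            "income_ha_yr": econ.income_per_ha_year,
        }]).to_csv(out / "preselection.csv", index=False)
        logline(f"preselect: gain {sim.percent_gain:.2f}%")
        artifacts["preselection"] = out / "preselection.csv"

    return artifacts


def merge_tables(a, b):
    """Stack two disjoint per-group tables into one (SNP ids prefixed)."""
    from .core import GenotypeTable
    snps_a = a.snps.assign(snp_id="A_" + a.snps["snp_id"].astype(str))
    snps_b = b.snps.assign(snp_id="B_" + b.snps["snp_id"].astype(str))
    n_a, n_b = a.n_individuals, b.n_individuals
    dosage = np.full((n_a + n_b, a.n_snps + b.n_snps), np.nan)
    dosage[:n_a, :a.n_snps] = a.dosage
    dosage[n_a:, a.n_snps:] = b.dosage
    depth = np.zeros_like(dosage)
    if a.depth is not None:
        depth[:n_a, :a.n_snps] = a.depth
    if b.depth is not None:
        depth[n_a:, a.n_snps:] = b.depth
    groups = np.concatenate([
        a.groups if a.groups is not None else np.array(["A"] * n_a, dtype=object),
        b.groups if b.groups is not None else np.array(["B"] * n_b, dtype=object)])
    return GenotypeTable(ids=a.ids + b.ids,
                         snps=pd.concat([snps_a, snps_b], ignore_index=True),
                         dosage=dosage, depth=depth, groups=groups)


def merge_pedigrees(a, b):
    from .core import Pedigree
    return Pedigree(pd.concat([a.records, b.records], ignore_index=True))
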