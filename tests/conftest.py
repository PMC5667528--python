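import numpy as np
import pandas as pd
import pytest

from hybridgs import (PopulationSpec, simulate_breeding_population,
                      simulate_mating_design, simulate_phenotypes)
from hybridgs.core import GenotypeTable, MatingDesign, Pedigree
from hybridgs.pipeline import merge_tables
from hybridgs.simulate import SimVarianceComponents, TrialLayout


def make_genotypes(dosage, ids=None, depth=None, groups=None):
    """GenotypeTable from a plain dosage array (one fake locus per column)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ids = ids or [f"i{k}" for k in range(n)]
    snps = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": "1", "pos": np.arange(1, m + 1) * 100,
        "ref": "A", "alt": "T",
    })
    return GenotypeTable(ids=ids, snps=snps, dosage=dosage, depth=depth,
                         groups=None if groups is None
                         else np.asarray(groups, dtype=object))


@pytest.fixture(scope="session")
def toy_pedigree():
    """Founders s, d; full sibs c1, c2; a selfed offspring of s."""
    return Pedigree(pd.DataFrame({
        "id": ["s", "d", "c1", "c2", "self1"],
        "sire": ["0", "0", "s", "s", "s"],
        "dam": ["0", "0", "d", "d", "s"],
        "group": "A", "generation": [0, 0, 1, 1, 1],
    }))


@pytest.fixture(scope="session")
def two_group_sim():
    """A small but complete two-group scenario with clean genotypes.

    Last-generation individuals of each group serve as hybrid parents; the
    phenotypes follow the generating GCA/SCA variance structure with
    marker-borne GCAs.
    """
    spec_a = PopulationSpec("A", n_founders=4, n_generations=2,
                            n_individuals_per_generation=16, n_snps=150,
                            seed=21, gbs_noise=False)
    spec_b = PopulationSpec("B", n_founders=4, n_generations=2,
                            n_individuals_per_generation=16, n_snps=150,
                            seed=22, gbs_noise=False)
    ped_a, gt_a = simulate_breeding_population(spec_a)
    ped_b, gt_b = simulate_breeding_population(spec_b)
    genotypes = merge_tables(gt_a, gt_b)
    parents_a = ped_a.group_ids("A")[-12:]
    parents_b = ped_b.group_ids("B")[-12:]
    design = simulate_mating_design(parents_a, parents_b, 4, seed=5)
    components = SimVarianceComponents(var_sca=3.0)
    layout = TrialLayout(n_trials=1, n_blocks=3, palms_per_plot=2,
                         ages=(3, 4, 5))
    phenotypes, truth = simulate_phenotypes(design, ped_a, ped_b, genotypes,
                                            components, layout, seed=7)
    return dict(ped_a=ped_a, ped_b=ped_b, genotypes=genotypes, design=design,
                phenotypes=phenotypes, truth=truth, components=components)
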