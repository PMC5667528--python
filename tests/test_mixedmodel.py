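"""Henderson MME, REML and prediction against dense independent oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_genotypes
from hybridgs.core import GammaStructure, MatingDesign, Pedigree, RelationshipMatrix
from hybridgs.mixedmodel import (MMESystem, ModelSpec, RandomTerm,
                                 VarianceComponents, accuracy_from_pev,
                                 build_design, dominance_proportion,
                                 fit_model, genomic_predict, identity_gammas,
                                 pedigree_gammas, reference_values,
                                 reml_estimate, solve_mme)
from hybridgs.relmat import vanraden_G


def onecross_design():
    return MatingDesign(pd.DataFrame([("c1", "a1", "b1")],
                                     columns=["cross", "parent_a", "parent_b"]))


def simple_phenotypes(values, cross="c1"):
    n = len(values)
    return pd.DataFrame({
        "cross": cross, "trial": "T0", "block": "B0",
        "incomplete_block": None, "plot": [f"p{i}" for i in range(n)],
        "individual": [f"i{i}" for i in range(n)], "age": None,
        "trait": "y", "value": values,
    })


class TestSolveMME:
    def test_no_random_terms_equals_ols(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(12), rng.standard_normal(12)])
        y = X @ [2.0, -1.0] + rng.standard_normal(12)
        system = MMESystem(y=y, X=X, fixed_names=["mu", "x"], terms=[])
        fit = solve_mme(system, VarianceComponents({}, 1.0))
        expect = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta.to_numpy(), expect, atol=1e-10)

    def test_matches_dense_gls_blup_oracle(self):
        """8-observation toy with one correlated random term: solutions
        equal BLUE/BLUP computed by direct inversion of V."""
        rng = np.random.default_rng(1)
        n, q = 8, 3
        X = np.ones((n, 1))
        Z = np.zeros((n, q))
        Z[np.arange(n), np.arange(n) % q] = 1.0
        M = rng.standard_normal((q, q))
        G = M @ M.T / q + np.eye(q)
        y = rng.standard_normal(n) * 2 + 5
        s2g, s2e = 1.7, 0.9
        term = RandomTerm("g", Z, [f"g{i}" for i in range(q)],
                          Ginv=np.linalg.inv(G))
        fit = solve_mme(MMESystem(y, X, ["mu"], [term]),
                        VarianceComponents({"g": s2g}, s2e))
        V = s2g * Z @ G @ Z.T + s2e * np.eye(n)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = s2g * G @ Z.T @ Vi @ (y - X @ beta)
        assert fit.beta["mu"] == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(fit.solutions["g"].to_numpy(), u, atol=1e-8)
        assert fit.mme_residual <= 1e-8

    def test_pev_within_bounds_and_zero_data_limit(self):
        Z = np.eye(4)
        G = np.eye(4)
        term = RandomTerm("g", Z, list("abcd"), Ginv=G, gamma_diag=np.ones(4))
        y = np.zeros(4)
        fit = solve_mme(MMESystem(y, np.ones((4, 1)), ["mu"], [term]),
                        VarianceComponents({"g": 2.0}, 1.0))
        pev = fit.pev["g"].to_numpy()
        assert ((pev >= 0) & (pev <= 2.0 + 1e-9)).all()

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(9)
        Z = np.zeros((9, 3))
        Z[np.arange(9), np.arange(9) % 3] = 1.0
        term = lambda: RandomTerm("g", Z, list("abc"), Ginv=np.eye(3))
        vc = VarianceComponents({"g": 1.0}, 1.0)
        f1 = solve_mme(MMESystem(y, np.ones((9, 1)), ["mu"], [term()]), vc)
        f2 = solve_mme(MMESystem(y + 100.0, np.ones((9, 1)), ["mu"], [term()]), vc)
        assert f2.beta["mu"] - f1.beta["mu"] == pytest.approx(100.0, abs=1e-8)
        np.testing.assert_allclose(f1.solutions["g"], f2.solutions["g"],
                                   atol=1e-8)


class TestBuildDesign:
    def test_single_trial_block_drops_nested_terms(self):
        phen = simple_phenotypes([1.0, 2.0, 3.0])
        system = build_design(phen, onecross_design(),
                              identity_gammas(onecross_design()))
        names = [t.name for t in system.terms]
        assert "incomplete_block" not in names
        assert system.X.shape[1] == 1  # mean only

    def test_age_by_cross_column_count(self):
        rows = []
        md = MatingDesign(pd.DataFrame(
            [("c1", "a1", "b1"), ("c2", "a2", "b2")],
            columns=["cross", "parent_a", "parent_b"]))
        for c in ("c1", "c2"):
            for age in (3, 4):
                for i in range(2):
                    rows.append((c, "T0", "B0", None, f"{c}pl{i}", f"{c}i{i}",
                                 age, "y", 1.0))
        phen = pd.DataFrame(rows, columns=["cross", "trial", "block",
                                           "incomplete_block", "plot",
                                           "individual", "age", "trait",
                                           "value"])
        system = build_design(phen, md, identity_gammas(md))
        assert system.term("age_cross").n_levels == 4  # 2 ages x 2 crosses

    def test_level_counts_match_enumeration(self, two_group_sim):
        s = two_group_sim
        system = build_design(s["phenotypes"], s["design"],
                              identity_gammas(s["design"]))
        df = s["phenotypes"]
        assert system.term("plot").n_levels == df["plot"].nunique()
        assert system.term("individual").n_levels == df["individual"].nunique()
        assert system.term("gA").n_levels == len(s["design"].parents_a)
        n_ages = df["age"].nunique()
        assert system.term("age_cross").n_levels == \
            n_ages * len(s["design"].cross_ids)

    def test_unknown_cross_rejected(self):
        phen = simple_phenotypes([1.0, 2.0, 3.0], cross="ghost")
        with pytest.raises(ValueError, match="unknown cross"):
            build_design(phen, onecross_design(),
                         identity_gammas(onecross_design()))


class TestREML:
    def test_balanced_one_way_matches_anova_closed_form(self):
        """Textbook oracle: REML of a balanced one-way random model equals
        sigma2_e = MSE and sigma2_a = (MSA - MSE) / r."""
        rng = np.random.default_rng(3)
        m, r = 12, 5
        a = rng.normal(0, 2.0, m)
        y = np.repeat(a, r) + rng.normal(0, 1.0, m * r)
        Z = np.kron(np.eye(m), np.ones((r, 1)))
        term = RandomTerm("a", Z, [f"g{i}" for i in range(m)])
        system = MMESystem(y, np.ones((m * r, 1)), ["mu"], [term])
        vc, info = reml_estimate(system, method="ai")
        ybar_i = y.reshape(m, r).mean(axis=1)
        msa = r * np.sum((ybar_i - y.mean())**2) / (m - 1)
        mse = np.sum((y.reshape(m, r) - ybar_i[:, None])**2) / (m * (r - 1))
        assert info["converged"]
        assert vc.residual == pytest.approx(mse, rel=1e-4)
        assert vc.by_term["a"] == pytest.approx((msa - mse) / r, rel=1e-4)

    def test_em_and_ai_agree(self):
        rng = np.random.default_rng(4)
        m, r = 8, 4
        y = np.repeat(rng.normal(0, 1.5, m), r) + rng.normal(0, 1.0, m * r)
        Z = np.kron(np.eye(m), np.ones((r, 1)))
        mk = lambda: MMESystem(y, np.ones((m * r, 1)), ["mu"],
                               [RandomTerm("a", Z, [f"g{i}" for i in range(m)])])
        vc_em, _ = reml_estimate(mk(), method="em", max_iter=2000)
        vc_ai, _ = reml_estimate(mk(), method="ai")
        assert vc_em.residual == pytest.approx(vc_ai.residual, rel=1e-3)
        assert vc_em.by_term["a"] == pytest.approx(vc_ai.by_term["a"], rel=1e-3)

    def test_em_loglik_nondecreasing(self):
        rng = np.random.default_rng(5)
        m, r = 6, 3
        y = np.repeat(rng.normal(0, 1.0, m), r) + rng.normal(0, 1.0, m * r)
        Z = np.kron(np.eye(m), np.ones((r, 1)))
        system = MMESystem(y, np.ones((m * r, 1)), ["mu"],
                           [RandomTerm("a", Z, [f"g{i}" for i in range(m)])])
        _, info = reml_estimate(system, method="em", max_iter=60)
        ll = np.array(info["loglik_path"])
        assert (np.diff(ll) >= -1e-8).all()

    def test_pure_noise_gives_null_genetic_components(self):
        rng = np.random.default_rng(6)
        md = MatingDesign(pd.DataFrame(
            [(f"c{a}{b}", f"a{a}", f"b{b}") for a in range(5) for b in range(5)],
            columns=["cross", "parent_a", "parent_b"]))
        rows = []
        for c in md.cross_ids:
            for i in range(6):
                rows.append((c, "T0", "B0", None, f"{c}p{i}", f"{c}i{i}",
                             None, "y", rng.normal(0, 3.0)))
        phen = pd.DataFrame(rows, columns=["cross", "trial", "block",
                                           "incomplete_block", "plot",
                                           "individual", "age", "trait", "value"])
        system = build_design(phen, md, identity_gammas(md),
                              ModelSpec(include_plot=False,
                                        include_individual=False))
        vc, _ = reml_estimate(system, method="ai")
        for name in ("gA", "gB", "sAB"):
            assert vc.by_term[name] <= 0.05 * vc.residual


class TestPredictions:
    def test_reference_value_equals_adjusted_cross_mean(self):
        rng = np.random.default_rng(7)
        y = rng.normal(10.0, 1.0, 10)
        phen = simple_phenotypes(y)
        pred, ga, gb, fit = reference_values(
            phen, onecross_design(), mode="cross_values",
            vc=VarianceComponents({"gA": 1.0, "gB": 1.0, "sAB": 1.0}, 1.0))
        assert pred.values["c1"] == pytest.approx(y.mean() - fit.beta["mu"],
                                                  abs=1e-8)

    def test_identity_gammas_spread_exceeds_pedigree_shrinkage(self, two_group_sim):
        """Unshrunken cross values spread at least as widely as GCA sums
        shrunk towards family means through the pedigree."""
        s = two_group_sim
        vc = VarianceComponents({"plot": 10.0, "individual": 30.0,
                                 "gA": 25.0, "gB": 55.0, "sAB": 3.0,
                                 "age_cross": 5.0}, 80.0)
        p1, ga1, gb1, _ = reference_values(s["phenotypes"], s["design"],
                                           mode="cross_values", vc=vc)
        p2, ga2, gb2, _ = reference_values(s["phenotypes"], s["design"],
                                           s["ped_a"], s["ped_b"],
                                           mode="parental_gcas", vc=vc)
        pm = s["design"].parent_map()
        sums1 = pd.Series({c: ga1[a] + gb1[b] for c, (a, b) in pm.items()})
        sums2 = pd.Series({c: ga2[a] + gb2[b] for c, (a, b) in pm.items()})
        assert sums1.std() >= sums2.std() * 0.98

    def test_adjustment_beats_raw_means_under_design_effects(self, two_group_sim):
        s = two_group_sim
        true = s["truth"].cross_values(s["design"])
        pred, _, _, _ = reference_values(s["phenotypes"], s["design"],
                                         mode="cross_values")
        raw = s["phenotypes"].groupby("cross")["value"].mean()
        r_ref = np.corrcoef(pred.values[true.index], true)[0, 1]
        r_raw = np.corrcoef(raw[true.index], true)[0, 1]
        assert r_ref >= r_raw - 0.05

    def test_with_sca_false_is_exact_gca_sum(self, two_group_sim):
        s = two_group_sim
        vc = VarianceComponents({"plot": 10.0, "individual": 30.0,
                                 "gA": 25.0, "gB": 55.0, "sAB": 3.0,
                                 "age_cross": 5.0}, 80.0)
        pred, ga, gb, _ = genomic_predict(s["phenotypes"], s["design"],
                                          identity_gammas(s["design"]),
                                          with_sca=False, vc=vc)
        pm = s["design"].parent_map()
        for c, (a, b) in pm.items():
            assert pred.values[c] == ga[a] + gb[b]  # bitwise: no SCA added

    def test_unphenotyped_full_sibs_get_identical_pedigree_gcas(self):
        """Pedigree-only covariances cannot separate full sibs without own
        data: their predicted GCAs coincide."""
        ped_a = Pedigree(pd.DataFrame({
            "id": ["f1", "f2", "t1", "v1", "v2"],
            "sire": ["0", "0", "f1", "f1", "f1"],
            "dam": ["0", "0", "f2", "f2", "f2"],
            "group": "A", "generation": [0, 0, 1, 1, 1]}))
        ped_b = Pedigree(pd.DataFrame({
            "id": ["g1", "g2", "u1"], "sire": ["0", "0", "g1"],
            "dam": ["0", "0", "g2"], "group": "B", "generation": [0, 0, 1]}))
        md = MatingDesign(pd.DataFrame([("c1", "t1", "u1")],
                                       columns=["cross", "parent_a", "parent_b"]))
        rng = np.random.default_rng(8)
        phen = simple_phenotypes(rng.normal(5, 1, 8))
        gammas = pedigree_gammas(md, ped_a, ped_b,
                                 parents_a=["t1", "v1", "v2"],
                                 parents_b=["u1"])
        vc = VarianceComponents({"gA": 2.0, "gB": 2.0, "sAB": 1.0}, 1.0)
        _, ga, _, _ = genomic_predict(phen, md, gammas, vc=vc)
        assert ga["v1"] == pytest.approx(ga["v2"], abs=1e-10)
        assert ga["v1"] != 0.0

    def test_gblup_equals_snp_blup_ridge_oracle(self):
        """Equivalent-model identity: GBLUP breeding values equal W a_hat
        from ridge regression on centred dosages with matched variances."""
        rng = np.random.default_rng(9)
        n_ind, n_snp, n_obs_per = 20, 60, 3
        D = rng.integers(0, 3, (n_ind, n_snp)).astype(float)
        D[0], D[1] = 0.0, 2.0
        gt = make_genotypes(D)
        G = vanraden_G(gt)
        p = D.mean(axis=0) / 2
        W = D - 2 * p
        c = 2 * np.sum(p * (1 - p))
        ids = gt.ids
        Z = np.kron(np.eye(n_ind), np.ones((n_obs_per, 1)))
        g_true = W @ rng.normal(0, 0.2, n_snp)
        y = 3.0 + Z @ g_true + rng.normal(0, 1.0, n_ind * n_obs_per)
        s2g, s2e = float(np.var(g_true)), 1.0
        term = RandomTerm("g", Z, ids, Ginv=np.linalg.inv(
            G.values + 1e-9 * np.eye(n_ind)))
        fit = solve_mme(MMESystem(y, np.ones((len(y), 1)), ["mu"], [term]),
                        VarianceComponents({"g": s2g}, s2e))
        # SNP-BLUP oracle: MME on marker effects with s2_a = s2_g / c
        Wz = Z @ W
        lam = s2e / (s2g / c)
        A = np.block([[np.full((1, 1), len(y)), Wz.sum(axis=0)[None, :]],
                      [Wz.sum(axis=0)[:, None], Wz.T @ Wz + lam * np.eye(n_snp)]])
        rhs = np.concatenate([[y.sum()], Wz.T @ y])
        sol = np.linalg.solve(A, rhs)
        g_snp = W @ sol[1:]
        np.testing.assert_allclose(fit.solutions["g"].to_numpy(), g_snp,
                                   atol=1e-6)


class TestDerivedQuantities:
    def test_dominance_proportion_zero_without_sca(self):
        md = onecross_design()
        g = identity_gammas(md)
        vc = VarianceComponents({"gA": 1.0, "gB": 1.0, "sAB": 0.0}, 1.0)
        assert dominance_proportion(vc, g) == 0.0

    def test_dominance_proportion_identity_equal_variances(self):
        md = onecross_design()
        g = identity_gammas(md)
        vc = VarianceComponents({"gA": 1.0, "gB": 1.0, "sAB": 1.0}, 1.0)
        assert dominance_proportion(vc, g) == pytest.approx(1 / 3)

    def test_dominance_proportion_formula_reevaluation(self):
        rng = np.random.default_rng(10)
        na, nb = 4, 3
        mk = lambda n: (lambda M: M @ M.T / n + np.eye(n))(
            rng.standard_normal((n, n)))
        ga = RelationshipMatrix([f"a{i}" for i in range(na)], mk(na))
        gb = RelationshipMatrix([f"b{i}" for i in range(nb)], mk(nb))
        md = MatingDesign(pd.DataFrame(
            [(f"c{a}{b}", f"a{a}", f"b{b}") for a in range(na)
             for b in range(nb)], columns=["cross", "parent_a", "parent_b"]))
        from hybridgs.relmat import dominance_gamma
        gd = dominance_gamma(ga, gb, md)
        g = GammaStructure(ga, gb, gd)
        s2a, s2b, s2d = 2.0, 3.0, 1.5
        vc = VarianceComponents({"gA": s2a, "gB": s2b, "sAB": s2d}, 1.0)
        ta = np.trace(ga.values) / na
        tb = np.trace(gb.values) / nb
        td = np.trace(gd.values) / (na * nb)
        expect = td * s2d / (td * s2d + ta * s2a + tb * s2b)
        assert dominance_proportion(vc, g) == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("pev,expected", [
        (0.0, 1.0), (1.0, 0.0), (0.75, 0.5)])
    def test_accuracy_from_pev(self, pev, expected):
        assert accuracy_from_pev(pev, 1.0, 1.0) == pytest.approx(expected)

    def test_accuracy_from_pev_range_check(self):
        with pytest.raises(ValueError):
            accuracy_from_pev(1.2, 1.0, 1.0)
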