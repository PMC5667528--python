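"""Relationship-matrix constructions checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_genotypes
from hybridgs.core import MatingDesign, Pedigree, RelationshipMatrix
from hybridgs.relmat import (coancestry_summary, combined_gamma_inverse,
                             dominance_gamma, molecular_coancestry,
                             pedigree_relationship, read_matrix, vanraden_G,
                             write_matrix)


def recursive_kinship(ped: Pedigree):
    """Brute-force coancestry by the recursive definition (memoised)."""
    parents = {r["id"]: (None if r["sire"] == "0" else r["sire"],
                         None if r["dam"] == "0" else r["dam"])
               for _, r in ped.records.iterrows()}
    order = {i: k for k, i in enumerate(ped.ids)}
    cache = {}

    def f(x, y):
        if x is None or y is None:
            return 0.0
        key = (x, y) if order[x] <= order[y] else (y, x)
        if key in cache:
            return cache[key]
        if x == y:
            s, d = parents[x]
            val = 0.5 * (1.0 + f(s, d))
        else:
            # recurse on the younger individual
            if order[x] < order[y]:
                x, y = y, x
            s, d = parents[x]
            val = 0.5 * (f(s, y) + f(d, y))
        cache[key] = val
        return val

    return f


class TestPedigreeRelationship:
    def test_full_sibs_of_unrelated_parents(self, toy_pedigree):
        A = pedigree_relationship(toy_pedigree)
        assert A.loc(["c1"], ["c2"])[0, 0] == pytest.approx(0.5)  # f = 0.25

    def test_noninbred_self_relationship(self, toy_pedigree):
        A = pedigree_relationship(toy_pedigree)
        assert A.loc(["s"])[0, 0] == pytest.approx(1.0)  # f(x,x) = 0.5

    def test_selfing_offspring_diagonal(self, toy_pedigree):
        A = pedigree_relationship(toy_pedigree)
        assert A.loc(["self1"])[0, 0] == pytest.approx(1.5)  # F = 0.5

    def test_subject_selection_orders_matrix(self, toy_pedigree):
        A = pedigree_relationship(toy_pedigree, subjects=["c2", "s"])
        assert A.ids == ["c2", "s"]
        assert A.values[0, 1] == pytest.approx(0.5)  # parent-offspring

    def test_unknown_subject_rejected(self, toy_pedigree):
        with pytest.raises(KeyError):
            pedigree_relationship(toy_pedigree, subjects=["nope"])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_recursive_definition_on_random_pedigrees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        rows = []
        for i in range(n):
            if i < 3:
                s = d = "0"
            else:
                s = f"x{rng.integers(i)}"
                d = f"x{rng.integers(i)}" if rng.random() > 0.2 else s
            rows.append((f"x{i}", s, d, "A", i))
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam",
                                                   "group", "generation"]))
        A = pedigree_relationship(ped)
        f = recursive_kinship(ped)
        expect = np.array([[2.0 * f(x, y) for y in ped.ids] for x in ped.ids])
        np.testing.assert_allclose(A.values, expect, atol=1e-12)


class TestMolecularCoancestry:
    @pytest.mark.parametrize("d1,d2,expected", [
        ([0, 0], [2, 2], 0.0),     # opposite homozygotes everywhere
        ([1, 1], [1, 1], 0.5),     # shared heterozygotes
        ([0, 0], [1, 0], 0.75),    # AA/AB then AA/AA: (0.5 + 1)/2
    ])
    def test_hand_enumerated_similarity(self, d1, d2, expected):
        gt = make_genotypes(np.array([d1, d2], dtype=float))
        S = molecular_coancestry(gt)
        assert S.values[0, 1] == pytest.approx(expected)

    def test_no_shared_locus_flagged_missing(self):
        gt = make_genotypes(np.array([[0.0, np.nan], [np.nan, 2.0]]))
        S = molecular_coancestry(gt)
        assert np.isnan(S.values[0, 1])


class TestVanRadenG:
    def test_single_snp_forced_values(self):
        gt = make_genotypes([[0.0], [2.0]])
        G = vanraden_G(gt)
        np.testing.assert_allclose(G.values, [[2, -2], [-2, 2]])

    def test_duplicated_individual_rows_identical(self):
        rng = np.random.default_rng(0)
        D = rng.integers(0, 3, (5, 30)).astype(float)
        D[1], D[2] = 0.0, 2.0  # keep every column polymorphic
        D[4] = D[0]
        G = vanraden_G(make_genotypes(D))
        np.testing.assert_allclose(G.values[0], G.values[4])
        assert G.values[0, 4] == pytest.approx(G.values[0, 0])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        D = rng.integers(0, 3, (20, 50)).astype(float)
        # guard against monomorphic columns
        D[0] = 0.0
        D[1] = 2.0
        gt = make_genotypes(D)
        G = vanraden_G(gt)
        p = D.mean(axis=0) / 2
        denom = 2 * np.sum(p * (1 - p))
        expect = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                expect[i, j] = np.sum((D[i] - 2 * p) * (D[j] - 2 * p)) / denom
        np.testing.assert_allclose(G.values, expect, rtol=1e-10)

    def test_invariant_to_snp_and_individual_order(self):
        rng = np.random.default_rng(2)
        D = rng.integers(0, 3, (8, 40)).astype(float)
        D[0], D[1] = 0.0, 2.0
        G = vanraden_G(make_genotypes(D))
        perm_snp = rng.permutation(40)
        perm_ind = rng.permutation(8)
        G2 = vanraden_G(make_genotypes(D[np.ix_(perm_ind, perm_snp)]))
        np.testing.assert_allclose(G2.values,
                                   G.values[np.ix_(perm_ind, perm_ind)],
                                   atol=1e-12)

    def test_monomorphic_snp_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_G(make_genotypes([[1.0, 0.0], [1.0, 2.0]]))

    def test_missing_dosage_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            vanraden_G(make_genotypes([[np.nan], [2.0]]))


@pytest.fixture(scope="module")
def six_pedigree():
    """Six individuals over three generations; p4, p5, p6 are genotyped."""
    return Pedigree(pd.DataFrame({
        "id": ["p1", "p2", "p3", "p4", "p5", "p6"],
        "sire": ["0", "0", "p1", "p1", "p3", "p3"],
        "dam": ["0", "0", "p2", "p2", "p4", "p4"],
        "group": "A", "generation": [0, 0, 1, 1, 2, 2],
    }))


class TestCombinedGamma:
    def test_no_genotyped_reduces_to_half_A(self, six_pedigree):
        A = pedigree_relationship(six_pedigree)
        comb = combined_gamma_inverse(A, None, [])
        np.testing.assert_allclose(comb.gamma.values, 0.5 * A.values,
                                   atol=1e-8)

    def test_all_genotyped_reduces_to_conditioned_G(self, six_pedigree):
        rng = np.random.default_rng(3)
        D = rng.integers(0, 3, (6, 60)).astype(float)
        D[0], D[1] = 0.0, 2.0
        gt = make_genotypes(D, ids=list(six_pedigree.ids))
        G = vanraden_G(gt)
        A = pedigree_relationship(six_pedigree)
        comb = combined_gamma_inverse(A, G, list(six_pedigree.ids),
                                      blend_weight=0.95)
        Gstar = 0.95 * G.values + 0.05 * 0.5 * A.values
        got = comb.gamma.reorder(list(six_pedigree.ids)).values
        np.testing.assert_allclose(got, Gstar, atol=1e-8)

    def test_partial_matches_conditional_expectation_oracle(self, six_pedigree):
        """Dense oracle: Gamma_11 = a11 + a12 a22^-1 (G - a22) a22^-1 a21,
        Gamma_12 = a12 a22^-1 G, Gamma_22 = G, with a = 0.5 A."""
        rng = np.random.default_rng(4)
        genotyped = ["p4", "p5", "p6"]
        D = rng.integers(0, 3, (3, 80)).astype(float)
        D[0], D[1] = 0.0, 2.0
        gt = make_genotypes(D, ids=genotyped)
        G = vanraden_G(gt)
        A = pedigree_relationship(six_pedigree)
        w = 0.99
        comb = combined_gamma_inverse(A, G, genotyped, blend_weight=w)
        non = [i for i in six_pedigree.ids if i not in genotyped]
        order = non + genotyped
        a = 0.5 * A.loc(order)
        n1 = len(non)
        a11, a12, a22 = a[:n1, :n1], a[:n1, n1:], a[n1:, n1:]
        Gs = w * G.loc(genotyped) + (1 - w) * a22
        a22i = np.linalg.inv(a22)
        expect = np.block([
            [a11 + a12 @ a22i @ (Gs - a22) @ a22i @ a12.T, a12 @ a22i @ Gs],
            [Gs @ a22i @ a12.T, Gs],
        ])
        np.testing.assert_allclose(comb.gamma.values, expect, atol=1e-7)

    def test_wrong_G_coverage_rejected(self, six_pedigree):
        A = pedigree_relationship(six_pedigree)
        G = RelationshipMatrix(["p4", "p5"], np.eye(2), "genomic_G")
        with pytest.raises(ValueError, match="exactly"):
            combined_gamma_inverse(A, G, ["p4", "p5", "p6"])


class TestDominanceGamma:
    def _design(self, na, nb):
        rows = [(f"c{a}{b}", f"a{a}", f"b{b}")
                for a in range(na) for b in range(nb)]
        return MatingDesign(pd.DataFrame(rows,
                                         columns=["cross", "parent_a", "parent_b"]))

    def test_identity_gammas_give_identity(self):
        md = self._design(2, 2)
        ga = RelationshipMatrix(["a0", "a1"], np.eye(2))
        gb = RelationshipMatrix(["b0", "b1"], np.eye(2))
        np.testing.assert_allclose(dominance_gamma(ga, gb, md).values,
                                   np.eye(4))

    def test_product_rule(self):
        md = MatingDesign(pd.DataFrame(
            [("c1", "a0", "b0"), ("c2", "a1", "b1")],
            columns=["cross", "parent_a", "parent_b"]))
        ga = RelationshipMatrix(["a0", "a1"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        gb = RelationshipMatrix(["b0", "b1"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        gd = dominance_gamma(ga, gb, md)
        assert gd.values[0, 1] == pytest.approx(0.25)

    def test_full_factorial_equals_kronecker(self):
        rng = np.random.default_rng(5)
        M = rng.standard_normal((3, 5))
        ga_v = M @ M.T / 5 + np.eye(3)
        N = rng.standard_normal((3, 5))
        gb_v = N @ N.T / 5 + np.eye(3)
        ga = RelationshipMatrix([f"a{i}" for i in range(3)], ga_v)
        gb = RelationshipMatrix([f"b{i}" for i in range(3)], gb_v)
        md = self._design(3, 3)
        gd = dominance_gamma(ga, gb, md)
        np.testing.assert_allclose(gd.values, np.kron(ga_v, gb_v), atol=1e-12)
        assert np.trace(gd.values) == pytest.approx(
            np.trace(ga_v) * np.trace(gb_v), rel=1e-12)

    def test_missing_parent_rejected(self):
        md = self._design(2, 2)
        ga = RelationshipMatrix(["a0"], np.eye(1))
        gb = RelationshipMatrix(["b0", "b1"], np.eye(2))
        with pytest.raises(KeyError):
            dominance_gamma(ga, gb, md)


class TestCoancestrySummary:
    def test_full_sib_validation(self, toy_pedigree):
        A = pedigree_relationship(toy_pedigree)
        s = coancestry_summary(A, ["c2"], ["c1"])
        assert s.mean == pytest.approx(0.25)

    def test_self_in_training(self, toy_pedigree):
        A = pedigree_relationship(toy_pedigree)
        s = coancestry_summary(A, ["c1"], ["c1", "d"])
        assert s.per_validation["c1"] >= 0.5

    def test_unrelated_founders_zero(self, toy_pedigree):
        A = pedigree_relationship(toy_pedigree)
        s = coancestry_summary(A, ["s"], ["d"])
        assert s.max == pytest.approx(0.0)

    def test_empty_training_rejected(self, toy_pedigree):
        A = pedigree_relationship(toy_pedigree)
        with pytest.raises(ValueError):
            coancestry_summary(A, ["s"], [])


def test_matrix_text_round_trip(tmp_path, toy_pedigree):
    A = pedigree_relationship(toy_pedigree)
    path = tmp_path / "A.tsv"
    write_matrix(A, path)
    back = read_matrix(path)
    assert back.ids == A.ids
    assert back.kind == "pedigree_A"
    np.testing.assert_allclose(back.values, A.values)
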