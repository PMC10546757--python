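"""Conventional SS-GBLUP baseline: G construction, H inverse, MME solves."""

import numpy as np
import pytest

import ssnnmm as sm
from ssnnmm.baseline import (
    backsolve_marker_effects,
    genomic_matrix,
    h_inverse,
    solve_gblup,
    solve_single_step,
)
from ssnnmm.data import GenotypeMatrix, PhenotypeTable
from ssnnmm.pedigree import relationship, submatrix
from ssnnmm.simulate import assign_roles

from conftest import make_pedigree


def _geno(ids, Z):
    Z = np.asarray(Z, dtype=float)
    return GenotypeMatrix(
        tuple(ids), tuple(f"M{j}" for j in range(Z.shape[1])), Z, np.ones(Z.shape, dtype=bool)
    )


class TestGenomicMatrix:
    def test_vanraden_hand_case(self):
        geno = _geno(["a", "b"], [[0, 2], [2, 0]])
        gm = genomic_matrix(geno, 0.95, 0.05, A22=np.eye(2))
        np.testing.assert_allclose(gm.G_raw, [[2.0, -2.0], [-2.0, 2.0]])
        np.testing.assert_allclose(gm.G_blend, 0.95 * gm.G_raw + 0.05 * np.eye(2))

    def test_centered_matrix_zero_gives_blended_a22(self):
        geno = _geno(["a", "b", "c"], [[1, 1], [1, 1], [1, 1]])
        A22 = np.eye(3)
        gm = genomic_matrix(geno, 0.95, 0.05, A22)
        np.testing.assert_allclose(gm.G_raw, 0.0)
        np.testing.assert_allclose(gm.G_blend, 0.05 * A22)

    def test_pure_g_blend_returns_g_raw(self):
        rng = np.random.default_rng(1)
        geno = _geno([f"i{k}" for k in range(20)], rng.integers(0, 3, size=(20, 100)))
        gm = genomic_matrix(geno, 1.0, 0.0)
        np.testing.assert_array_equal(gm.G_blend, gm.G_raw)

    def test_missing_cells_rejected(self):
        Z = np.ones((3, 2))
        mask = np.ones((3, 2), dtype=bool)
        mask[0, 0] = False
        geno = GenotypeMatrix(("a", "b", "c"), ("M0", "M1"), Z, mask)
        with pytest.raises(ValueError, match="common panel"):
            genomic_matrix(geno, 1.0, 0.0)


class TestHInverse:
    def test_g_equal_a22_collapses_to_a_inverse(self, fullsib_mating):
        nm = relationship(fullsib_mating)
        gen = ["3", "4", "5"]
        A22 = submatrix(nm, gen)
        H = h_inverse(nm.A_inv, A22, A22, fullsib_mating.index_of(gen), ids=fullsib_mating.ids)
        np.testing.assert_allclose(H.H_inv, nm.A_inv, atol=1e-10)

    def test_no_genotyped_individuals_collapses_to_a_inverse(self, trio):
        nm = relationship(trio)
        H = h_inverse(nm.A_inv, np.zeros((0, 0)), np.zeros((0, 0)), [], ids=trio.ids)
        np.testing.assert_array_equal(H.H_inv, nm.A_inv)

    def test_matches_dense_h_from_mvn_conditioning(self, fullsib_mating):
        """Textbook H built via conditional expectations of non-genotyped on
        genotyped breeding values, then inverted densely."""
        ped = fullsib_mating
        nm = relationship(ped)
        gen = ["3", "4", "5"]
        non = ["1", "2"]
        gi = ped.index_of(gen)
        ni = ped.index_of(non)
        A11 = nm.A[np.ix_(ni, ni)]
        A12 = nm.A[np.ix_(ni, gi)]
        A22 = nm.A[np.ix_(gi, gi)]
        G = 0.7 * A22 + 0.3 * np.eye(3)  # an arbitrary PD stand-in genomic matrix
        A22i = np.linalg.inv(A22)
        H11 = A11 + A12 @ A22i @ (G - A22) @ A22i @ A12.T
        H12 = A12 @ A22i @ G
        Hd = np.zeros((5, 5))
        Hd[np.ix_(ni, ni)] = H11
        Hd[np.ix_(ni, gi)] = H12
        Hd[np.ix_(gi, ni)] = H12.T
        Hd[np.ix_(gi, gi)] = G
        H = h_inverse(nm.A_inv, G, A22, gi, ids=ped.ids)
        np.testing.assert_allclose(H.H_inv, np.linalg.inv(Hd), atol=1e-6)


class TestSolvers:
    def test_identity_g_shrinks_deviations_by_half(self):
        ids = ("a", "b", "c", "d")
        y = np.array([1.0, -1.0, 2.0])
        pheno = PhenotypeTable(ids, np.append(y, 0.0), ("train",) * 3 + ("test",))
        # construct G = I directly to get the scalar closed form
        from ssnnmm.baseline import GenomicMatrix

        gm = GenomicMatrix(
            ids=ids, G_raw=np.eye(4), G_blend=np.eye(4),
            allele_freq=np.array([]), blend=(1.0, 0.0),
            M=np.zeros((4, 0)), scale=1.0,
        )
        ebv = solve_gblup(pheno, gm, 1.0)
        mu_hat = np.mean([v for v in y]) * 3 / (3 + 0)  # solved jointly; check shrinkage
        # with G=I, lambda=1: a_i = (y_i - mu_hat)/2 for phenotyped, 0 otherwise
        resid = y - np.mean(y)
        np.testing.assert_allclose(
            [ebv["a"], ebv["b"], ebv["c"]], resid / 2.0, atol=1e-8
        )
        assert ebv["d"] == pytest.approx(0.0, abs=1e-10)

    def test_h_equal_a_inverse_is_pedigree_blup(self, fullsib_mating):
        nm = relationship(fullsib_mating)
        pheno = PhenotypeTable(
            fullsib_mating.ids, np.array([0.5, -0.2, 0.9, 0.1, 0.0]), ("train",) * 4 + ("test",)
        )
        from ssnnmm.baseline import HInverse, _animal_mme

        H = HInverse(ids=fullsib_mating.ids, H_inv=nm.A_inv)
        ebv = solve_single_step(pheno, H, 2.0)
        # oracle: dense animal-model MME with A^-1 directly
        a = _animal_mme(pheno.y[:4], np.arange(4), np.linalg.inv(nm.A), 2.0)
        np.testing.assert_allclose([ebv[i] for i in fullsib_mating.ids], a, atol=1e-8)

    def test_infinite_shrinkage_kills_ebvs(self, fullsib_mating):
        nm = relationship(fullsib_mating)
        from ssnnmm.baseline import HInverse

        pheno = PhenotypeTable(
            fullsib_mating.ids, np.array([0.5, -0.2, 0.9, 0.1, 0.3]), ("train",) * 5
        )
        H = HInverse(ids=fullsib_mating.ids, H_inv=nm.A_inv)
        ebv = solve_single_step(pheno, H, 1e9)
        assert max(abs(v) for v in ebv.values()) < 1e-5


@pytest.fixture(scope="module")
def sim():
    ped = sm.simulate_pedigree(40, 4, 2, seed=51)
    geno = sm.gene_drop(ped, 300, seed=52)
    pheno, truth = sm.simulate_phenotypes(geno, qtl_prop=0.05, h2=0.7, seed=53)
    pheno = assign_roles(pheno, ped, 40)
    return ped, geno, pheno, truth


class TestModelEquivalences:

    def test_gblup_equals_ridge_regression(self, sim):
        """G-based animal model and marker ridge are the same model when
        variances are matched (sigma2_alpha = sigma2_a / sum 2p(1-p))."""
        ped, geno, pheno, _ = sim
        gm = genomic_matrix(geno, 1.0, 0.0)
        ebv = solve_gblup(pheno, gm, 3.0 / 7.0)
        train = pheno.train_ids()
        test = pheno.test_ids()
        gr = {i: k for k, i in enumerate(geno.ids)}
        X = gm.M[[gr[i] for i in train]]
        y = pheno.y_of(train)
        lam = (3.0 / 7.0) * gm.scale
        alpha = np.linalg.solve(X.T @ X + lam * np.eye(geno.m), X.T @ (y - y.mean()))
        ridge_ebv = gm.M[[gr[i] for i in test]] @ alpha
        got = np.array([ebv[i] for i in test])
        assert np.corrcoef(got, ridge_ebv)[0, 1] > 0.999

    def test_single_step_with_everyone_genotyped_equals_gblup(self, sim):
        ped, geno, pheno, _ = sim
        nm = relationship(ped)
        A22 = submatrix(nm, list(geno.ids))
        gm = genomic_matrix(geno, 0.95, 0.05, A22)
        H = h_inverse(nm.A_inv, gm.G_blend, A22, ped.index_of(geno.ids), ids=ped.ids)
        ss = solve_single_step(pheno, H, 3.0 / 7.0)
        gb = solve_gblup(pheno, gm, 3.0 / 7.0)
        test = pheno.test_ids()
        r = np.corrcoef([ss[i] for i in test], [gb[i] for i in test])[0, 1]
        assert r > 0.99

    def test_backsolved_effects_recover_ridge_coefficients(self, sim):
        ped, geno, pheno, _ = sim
        gm = genomic_matrix(geno, 1.0, 0.0)
        ebv = solve_gblup(pheno, gm, 3.0 / 7.0)
        alpha_bs = backsolve_marker_effects(gm, ebv)
        train = pheno.train_ids()
        gr = {i: k for k, i in enumerate(geno.ids)}
        X = gm.M[[gr[i] for i in train]]
        y = pheno.y_of(train)
        lam = (3.0 / 7.0) * gm.scale
        alpha = np.linalg.solve(X.T @ X + lam * np.eye(geno.m), X.T @ (y - y.mean()))
        assert np.corrcoef(alpha_bs, alpha)[0, 1] > 0.99
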