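"""Gene-content layer: initialization, Gibbs/MME fixed points, variances."""

import numpy as np
import pytest

import ssnnmm as sm
from ssnnmm import gene_content
from ssnnmm.data import GenotypeMatrix, PhenotypeTable
from ssnnmm.engine import Chain, RunConfig
from ssnnmm.gene_content import (
    heritability_from_samples,
    init_gene_content_state,
    update_gene_content_variances,
    update_marker_mean_and_u,
)
from ssnnmm.testing import ZeroInnovationRNG

from conftest import random_pedigree


def _geno(ids, Z):
    Z = np.asarray(Z, dtype=float)
    return GenotypeMatrix(
        tuple(ids), tuple(f"M{j}" for j in range(Z.shape[1])), Z, np.ones(Z.shape, dtype=bool)
    )


def _chain_for(ped, geno, **cfg):
    """Chain whose phenotypes are irrelevant (all-train, zero effects)."""
    pheno = PhenotypeTable(geno.ids, np.zeros(geno.n), tuple(["train"] * geno.n))
    defaults = dict(chain_length=10, seed=1)
    defaults.update(cfg)
    return Chain(ped, geno, pheno, RunConfig(**defaults))


class TestInit:
    def test_observed_mean_and_variance(self):
        geno = _geno(["a", "b", "c", "d"], [[0], [1], [2], [1]])
        b = init_gene_content_state(geno, h2_fixed=0.5)
        assert b.mu_g[0] == pytest.approx(1.0)
        assert b.s2[0] == pytest.approx(2.0 / 3.0)
        assert b.var_u[0] == pytest.approx(b.var_eps[0])  # h2 = 0.5

    def test_fixed_ratio_pins_heritability(self):
        geno = _geno(["a", "b", "c"], [[0, 1], [1, 2], [2, 0]])
        b = init_gene_content_state(geno, h2_fixed=0.999)
        np.testing.assert_allclose(b.var_eps / b.var_u, 0.001 / 0.999)

    def test_single_observation_rejected(self):
        Z = np.array([[0.0], [1.0]])
        mask = np.array([[True], [False]])
        geno = GenotypeMatrix(("a", "b"), ("M0",), Z, mask)
        with pytest.raises(ValueError, match="observed genotype"):
            init_gene_content_state(geno)

    def test_monomorphic_marker_excluded_with_warning(self):
        geno = _geno(["a", "b", "c"], [[1, 0], [1, 1], [1, 2]])
        with pytest.warns(UserWarning, match="monomorphic"):
            b = init_gene_content_state(geno)
        assert b.marker_index.tolist() == [1]


class TestMeanAndDeviationUpdates:
    def test_scalar_shrinkage_on_independent_founders(self):
        """With A = I the conditional mean of an observed founder's deviation
        is h^2 times its centered dosage."""
        ped = sm.topological_order(
            sm.Pedigree(("a", "b"), np.array([-1, -1]), np.array([-1, -1]))
        )
        geno = _geno(["a", "b"], [[0], [2]])
        ch = _chain_for(ped, geno, h2_fixed=0.9)
        st = ch.state
        update_marker_mean_and_u(st, ZeroInnovationRNG())
        assert st.blocks.mu_g[0] == pytest.approx(1.0)
        np.testing.assert_allclose(st.U[:, 0], [-0.9, 0.9], atol=1e-12)

    def test_zero_innovation_sweeps_converge_to_dense_mme_solution(self):
        """Iterated conditional-mean updates are Gauss-Seidel on the MME."""
        ped = random_pedigree(3, n=25)
        rng = np.random.default_rng(4)
        mid_ids = list(ped.ids[:15])
        Z = rng.integers(0, 3, size=(15, 2)).astype(float)
        geno = _geno(mid_ids, Z)
        ch = _chain_for(ped, geno, h2_fixed=0.9)
        st = ch.state
        zero = ZeroInnovationRNG()
        for _ in range(400):
            update_marker_mean_and_u(st, zero)
        # dense MME oracle per marker
        Ainv = st.ainv_csr.toarray()
        q = ped.n
        W = np.zeros((15, q))
        W[np.arange(15), st.mid_to_ped] = 1.0
        for j in range(st.blocks.mu_g.size):
            lam = st.blocks.var_eps[j] / st.blocks.var_u[j]
            C = np.zeros((q + 1, q + 1))
            C[0, 0] = 15
            C[0, 1:] = W.sum(axis=0)
            C[1:, 0] = W.sum(axis=0)
            C[1:, 1:] = W.T @ W + lam * Ainv
            rhs = np.concatenate([[st.Z[:, j].sum()], W.T @ st.Z[:, j]])
            sol = np.linalg.solve(C, rhs)
            assert abs(st.blocks.mu_g[j] - sol[0]) < 1e-6
            np.testing.assert_allclose(st.U[:, j], sol[1:], atol=1e-6)

    def test_marker_subset_update_touches_only_selected_columns(self):
        ped = random_pedigree(5, n=20)
        rng = np.random.default_rng(6)
        geno = _geno(list(ped.ids), rng.integers(0, 3, size=(20, 3)).astype(float))
        ch = _chain_for(ped, geno)
        st = ch.state
        before = st.U.copy()
        update_marker_mean_and_u(st, ZeroInnovationRNG(), markers=[1])
        assert (st.U[:, [0, 2]] == before[:, [0, 2]]).all()
        assert not (st.U[:, 1] == before[:, 1]).all()


class TestVarianceUpdates:
    def test_fixed_mode_is_a_no_op(self):
        ped = random_pedigree(7, n=12)
        rng = np.random.default_rng(8)
        geno = _geno(list(ped.ids), rng.integers(0, 3, size=(12, 2)).astype(float))
        ch = _chain_for(ped, geno, h2_mode="fixed")
        st = ch.state
        vu, ve = st.blocks.var_u.copy(), st.blocks.var_eps.copy()
        update_gene_content_variances(st, np.random.default_rng(0))
        np.testing.assert_array_equal(st.blocks.var_u, vu)
        np.testing.assert_array_equal(st.blocks.var_eps, ve)

    def test_zero_deviations_collapse_to_prior_scale(self):
        ped = random_pedigree(9, n=12)
        rng = np.random.default_rng(10)
        geno = _geno(list(ped.ids), rng.integers(0, 3, size=(12, 2)).astype(float))
        ch = _chain_for(ped, geno, h2_mode="estimated", prior_df=4.0)
        st = ch.state
        st.U[:] = 0.0
        nu, q = 4.0, ped.n
        expected = nu * st.blocks.S_u / (nu + q)
        update_gene_content_variances(st, ZeroInnovationRNG())
        np.testing.assert_allclose(st.blocks.var_u, expected)


class TestHeritability:
    def test_constant_samples(self):
        assert heritability_from_samples([0.3], [0.1]) == pytest.approx(0.75)

    def test_mean_of_ratios_not_ratio_of_means(self):
        vu = np.array([1.0, 1.0])
        ve = np.array([0.1, 10.0])
        got = heritability_from_samples(vu, ve)
        assert got == pytest.approx(0.5 * (1 / 1.1 + 1 / 11.0))
        assert got != pytest.approx(2.0 / 12.1)

    def test_fixed_mode_summary_reports_h2_fixed_exactly(self, small_dataset):
        ped, geno, pheno, _ = small_dataset
        summ = sm.run_nnmm(ped, geno, pheno, RunConfig(chain_length=20, seed=2, h2_fixed=0.999))
        assert (summ.gene_content_h2 == 0.999).all()
        assert gene_content.gene_content_heritability(summ, 0) == 0.999
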