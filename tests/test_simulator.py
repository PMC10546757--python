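"""Gene-dropping simulator: pedigree structure, Mendelian inheritance,
trait construction and masking."""

import numpy as np
import pytest

import ssnnmm as sm
from ssnnmm.data import GenotypeMatrix
from ssnnmm.simulate import _drop_markers, assign_roles


def _random_dosages(n, m, seed):
    rng = np.random.default_rng(seed)
    Z = rng.integers(0, 3, size=(n, m)).astype(float)
    return GenotypeMatrix(
        tuple(f"I{i}" for i in range(n)),
        tuple(f"M{j}" for j in range(m)),
        Z,
        np.ones((n, m), dtype=bool),
    )


class TestSimulatePedigree:
    def test_one_generation_counts_and_parentage(self):
        ped = sm.simulate_pedigree(4, 1, 2, seed=1)
        assert ped.n == 8
        assert (ped.generation == 0).sum() == 4
        kids = np.nonzero(ped.generation == 1)[0]
        assert all(ped.generation[ped.sire[k]] == 0 for k in kids)
        assert all(ped.generation[ped.dam[k]] == 0 for k in kids)
        assert all(ped.sire[k] != ped.dam[k] for k in kids)

    def test_zero_generations_gives_founders_only(self):
        ped = sm.simulate_pedigree(10, 0, seed=3)
        assert ped.n == 10
        assert sm.inbreeding_coefficients(ped).sum() == 0.0

    def test_same_seed_reproduces_identical_pedigree(self):
        a = sm.simulate_pedigree(20, 3, 2, seed=7)
        b = sm.simulate_pedigree(20, 3, 2, seed=7)
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.sire, b.sire)
        np.testing.assert_array_equal(a.dam, b.dam)

    @pytest.mark.parametrize("bad", [{"n_founders": 1}, {"n_founders": 3}, {"n_generations": -1}])
    def test_impossible_configurations_rejected(self, bad):
        kwargs = {"n_founders": 4, "n_generations": 1, **bad}
        with pytest.raises(ValueError):
            sm.simulate_pedigree(**kwargs)


class TestGeneDrop:
    def test_mendelian_certainties(self):
        ped = sm.simulate_pedigree(20, 3, 2, seed=11)
        geno = sm.gene_drop(ped, 60, seed=12)
        Z, s, d = geno.Z, ped.sire, ped.dam
        kids = np.nonzero(s >= 0)[0]
        for i in kids:
            both0 = (Z[s[i]] == 0) & (Z[d[i]] == 0)
            both2 = (Z[s[i]] == 2) & (Z[d[i]] == 2)
            opposite = Z[s[i]] + Z[d[i]] == 2
            opposite &= np.abs(Z[s[i]] - Z[d[i]]) == 2
            assert (Z[i][both0] == 0).all()
            assert (Z[i][both2] == 2).all()
            assert (Z[i][opposite] == 1).all()

    def test_founder_dosage_mean_tracks_allele_frequency(self):
        ped = sm.simulate_pedigree(500, 0, seed=13)
        rng = np.random.default_rng(14)
        freqs = rng.uniform(0.1, 0.9, size=200)
        Z = _drop_markers(ped, freqs, rng)
        close = np.abs(Z.mean(axis=0) - 2 * freqs) < 0.1
        assert close.mean() >= 0.95

    def test_no_monomorphic_markers_and_determinism(self):
        ped = sm.simulate_pedigree(30, 2, 2, seed=15)
        a = sm.gene_drop(ped, 50, seed=16)
        b = sm.gene_drop(ped, 50, seed=16)
        assert (a.Z.std(axis=0) > 0).all()
        np.testing.assert_array_equal(a.Z, b.Z)

    def test_invalid_inputs_rejected(self):
        ped = sm.simulate_pedigree(4, 0, seed=1)
        with pytest.raises(ValueError):
            sm.gene_drop(ped, 0)
        with pytest.raises(ValueError):
            sm.gene_drop(ped, 10, freq_low=0.9, freq_high=0.1)


class TestSimulatePhenotypes:
    def test_qtl_count_matches_half_percent_of_panel(self):
        geno = _random_dosages(50, 10_000, seed=21)
        _, truth = sm.simulate_phenotypes(geno, qtl_prop=0.005, seed=22)
        assert truth.qtl_indices.size == 50

    def test_genetic_variance_exact_and_phenotypic_close(self):
        geno = _random_dosages(2000, 500, seed=23)
        pheno, truth = sm.simulate_phenotypes(geno, qtl_prop=0.02, h2=0.7, var_p=1.0, seed=24)
        assert truth.true_bv.var() == pytest.approx(0.7, abs=1e-10)
        assert pheno.y.var() == pytest.approx(1.0, abs=0.05)
        # breeding values are reproducible from QTL dosages and effects
        rebuilt = geno.Z[:, truth.qtl_indices] @ truth.qtl_effects
        np.testing.assert_allclose(rebuilt - rebuilt.mean(), truth.true_bv, atol=1e-10)

    def test_near_unit_heritability_limit(self):
        geno = _random_dosages(2000, 200, seed=25)
        pheno, truth = sm.simulate_phenotypes(geno, qtl_prop=0.05, h2=0.999, seed=26)
        assert np.corrcoef(pheno.y, truth.true_bv)[0, 1] > 0.999

    def test_mean_realized_heritability_across_replicates(self):
        h2s = []
        for rep in range(10):
            geno = _random_dosages(2000, 300, seed=300 + rep)
            pheno, truth = sm.simulate_phenotypes(geno, qtl_prop=0.01, h2=0.7, seed=400 + rep)
            h2s.append(truth.true_bv.var() / pheno.y.var())
        assert abs(np.mean(h2s) - 0.7) < 0.05

    def test_too_few_qtl_rejected(self):
        geno = _random_dosages(20, 50, seed=27)
        with pytest.raises(ValueError):
            sm.simulate_phenotypes(geno, qtl_prop=0.001)


class TestMasking:
    def test_individual_masking_counts_and_protection(self):
        geno = _random_dosages(3484, 5, seed=31)
        protected = list(geno.ids[:50])
        masked = sm.mask_individuals(geno, 0.5, protected_ids=protected, seed=32)
        fully_missing = (~masked.observed_mask).all(axis=1)
        assert fully_missing.sum() == 1717  # round(0.5 * 3434)
        assert not fully_missing[:50].any()
        # untouched input and all-or-nothing per row
        assert geno.observed_mask.all()
        assert ((~masked.observed_mask).sum(axis=1) % 5 == 0).all()

    def test_zero_proportion_is_identity(self):
        geno = _random_dosages(30, 4, seed=33)
        masked = sm.mask_individuals(geno, 0.0, seed=34)
        np.testing.assert_array_equal(masked.observed_mask, geno.observed_mask)

    def test_individual_masking_deterministic(self):
        geno = _random_dosages(100, 6, seed=35)
        a = sm.mask_individuals(geno, 0.3, seed=36)
        b = sm.mask_individuals(geno, 0.3, seed=36)
        np.testing.assert_array_equal(a.observed_mask, b.observed_mask)

    def test_cellwise_masking_exact_count(self):
        geno = _random_dosages(1000, 200, seed=37)
        masked = sm.mask_cells(geno, 0.5, seed=38)
        assert (~masked.observed_mask).sum() == 100_000
        b = sm.mask_cells(geno, 0.5, seed=38)
        np.testing.assert_array_equal(masked.observed_mask, b.observed_mask)

    def test_invalid_proportion_rejected(self):
        geno = _random_dosages(10, 3, seed=39)
        for bad in (-0.1, 1.0):
            with pytest.raises(ValueError):
                sm.mask_individuals(geno, bad)
            with pytest.raises(ValueError):
                sm.mask_cells(geno, bad)


class TestRoles:
    def test_youngest_generation_becomes_test_set(self):
        ped = sm.simulate_pedigree(10, 2, 2, seed=41)
        geno = sm.gene_drop(ped, 20, seed=42)
        pheno, _ = sm.simulate_phenotypes(geno, qtl_prop=0.1, seed=43)
        pheno = assign_roles(pheno, ped, 4)
        test = pheno.test_ids()
        assert len(test) == 4
        gen = dict(zip(ped.ids, ped.generation))
        assert all(gen[i] == ped.generation.max() for i in test)
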