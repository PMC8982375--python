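"""Phenotypes, relationship matrices, BLUP, BayesC, and selection."""

import numpy as np
import pandas as pd
import pytest

import breedsim as bs
from breedsim.exceptions import NotImplementedMethodError, ValidationError


def make_sim(n_loci=50, n_qtl=10, h2=0.5, n_chr=1, seed=0, maf=0.5):
    genome = bs.build_genome(n_chr=n_chr, n_loci=n_loci, maf=maf)
    phenome = bs.build_phenome(genome, n_qtl, vg=1.0, h2=h2, seed=seed)
    return bs.Simulation(genome, phenome, seed=seed)


class TestPhenotypes:
    def test_noiseless_phenotype_equals_true_bv(self):
        genome = bs.build_genome(n_chr=1, n_loci=10)
        phenome = bs.Phenome(np.ones((10, 1)), np.array([[1.0]]),
                             np.array([[0.0]]))
        sim = bs.Simulation(genome, phenome, seed=1)
        A = sim.founders(20)
        np.testing.assert_allclose(A.get_phenotypes(), A.get_BVs())

    def test_phenotypes_are_sticky(self):
        sim = make_sim(seed=2)
        A = sim.founders(10)
        np.testing.assert_array_equal(A.get_phenotypes(), A.get_phenotypes())

    def test_heritability_recovery_at_scale(self):
        sim = make_sim(n_loci=100, n_qtl=20, h2=0.3, seed=3)
        A = sim.founders(10_000)
        ratio = A.get_BVs()[:, 0].var() / A.get_phenotypes()[:, 0].var()
        assert abs(ratio - 0.3) < 0.03

    def test_diagonal_ve_gives_uncorrelated_residuals(self):
        genome = bs.build_genome(n_chr=1, n_loci=40)
        phenome = bs.build_phenome(genome, [5, 5], vg=[1.0, 1.0],
                                   h2=[0.4, 0.4], seed=4)
        sim = bs.Simulation(genome, phenome, seed=4)
        A = sim.founders(10_000)
        resid = A.get_phenotypes() - A.get_BVs()
        r = np.corrcoef(resid.T)[0, 1]
        assert abs(r) < 0.03


class TestRelationshipMatrices:
    def test_unrelated_founders_give_identity(self):
        ped = pd.DataFrame({"id": [1, 2, 3], "sire": [0, 0, 0],
                            "dam": [0, 0, 0]})
        np.testing.assert_array_equal(bs.compute_A(ped), np.eye(3))

    def test_parent_offspring_half(self):
        ped = pd.DataFrame({"id": [1, 2, 3], "sire": [0, 0, 1],
                            "dam": [0, 0, 2]})
        A = bs.compute_A(ped)
        assert A[0, 2] == 0.5 and A[1, 2] == 0.5 and A[2, 2] == 1.0

    def test_one_selfing_generation_diagonal(self):
        ped = pd.DataFrame({"id": [1, 2], "sire": [0, 1], "dam": [0, 1]})
        assert bs.compute_A(ped)[1, 1] == 1.5

    def test_offspring_before_parent_rejected(self):
        ped = pd.DataFrame({"id": [3, 1, 2], "sire": [1, 0, 0],
                            "dam": [2, 0, 0]})
        with pytest.raises(ValidationError):
            bs.compute_A(ped)

    def test_duplicate_genotypes_duplicate_g_rows(self):
        M = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]], dtype=float)
        G = bs.compute_G(M)
        np.testing.assert_allclose(G[0], G[1])
        np.testing.assert_allclose(G[0, 1], G[0, 0])

    def test_vanraden_mean_diagonal_near_one(self):
        sim = make_sim(n_loci=200, seed=5, maf=0.3)
        M = sim.founders(500).get_genotypes()
        G = bs.compute_G(M, p=np.full(200, 0.7))
        assert abs(np.diag(G).mean() - 1.0) < 0.05

    def test_g_matches_explicit_double_loop(self):
        rng = np.random.default_rng(6)
        M = rng.integers(0, 3, size=(15, 30)).astype(float)
        p = M.mean(axis=0) / 2.0
        G = bs.compute_G(M)
        Z = M - 2 * p
        denom = 2 * np.sum(p * (1 - p))
        brute = np.empty((15, 15))
        for i in range(15):
            for j in range(15):
                brute[i, j] = np.dot(Z[i], Z[j]) / denom
        np.testing.assert_allclose(G, brute, atol=1e-10)

    def test_monomorphic_matrix_rejected(self):
        with pytest.raises(ValidationError):
            bs.compute_G(np.full((4, 6), 2.0))


class TestBlup:
    def test_identity_kernel_shrinks_by_half(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(30)
        y -= y.mean()
        u = bs.solve_blup(y, np.eye(30), vg=1.0, ve=1.0)
        np.testing.assert_allclose(u, y / 2.0, atol=1e-9)

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(20)
        u = bs.solve_blup(y, np.eye(20), vg=1e-9, ve=1.0)
        np.testing.assert_allclose(u, 0.0, atol=1e-5)

    def test_nonpositive_genetic_variance_rejected(self):
        with pytest.raises(ValidationError):
            bs.solve_blup(np.ones(3), np.eye(3), vg=0.0, ve=1.0)

    def test_gblup_accuracy_dominates_phenotype(self):
        """EBV from GBLUP should predict true BV better than the raw
        phenotype does, in nearly every replicate."""
        wins = 0
        for rep in range(50):
            sim = make_sim(n_loci=100, n_qtl=20, h2=0.5, seed=100 + rep)
            A = sim.founders(200)
            y = A.get_phenotypes()[:, 0]
            bv = A.get_BVs()[:, 0]
            bs.genetic_evaluation(A, criteria="EBV", methods="GBLUP")
            ebv = A.get_EBVs()[:, 0]
            if np.corrcoef(ebv, bv)[0, 1] > np.corrcoef(y, bv)[0, 1]:
                wins += 1
        assert wins >= 45

    def test_pblup_runs_on_structured_pedigree(self):
        sim = make_sim(seed=9)
        A, B = sim.founders(10), sim.founders(20)
        off = bs.mate(A, B, nA=10, nB_per_A=2, replace_B=True)
        ebv = bs.genetic_evaluation(off, criteria="EBV", methods="PBLUP")
        assert ebv.shape == (20, 1)
        assert np.all(np.isfinite(ebv))

    def test_unsupported_methods_raise_not_implemented(self):
        sim = make_sim(seed=10)
        A = sim.founders(5)
        with pytest.raises(NotImplementedMethodError):
            bs.genetic_evaluation(A, criteria="EBV", methods="single-step")


class TestBayesC:
    def test_pi_one_returns_zero_effects(self):
        rng = np.random.default_rng(11)
        M = rng.integers(0, 3, (50, 10)).astype(float)
        fit = bs.bayesc(M, rng.standard_normal(50), pi=1.0, rng=rng)
        np.testing.assert_array_equal(fit["effects"], 0.0)
        np.testing.assert_array_equal(fit["ebv"], 0.0)

    def test_single_strong_qtl_has_top_inclusion(self):
        rng = np.random.default_rng(12)
        n, m, qtl = 500, 50, 17
        M = rng.binomial(2, 0.5, (n, m)).astype(float)
        y = 2.0 * M[:, qtl] + rng.standard_normal(n)
        fit = bs.bayesc(M, y, pi=0.9, chain_length=2000, burn_in=500,
                        vg=2.0, ve=1.0, rng=np.random.default_rng(13))
        assert int(np.argmax(fit["inclusion"])) == qtl

    def test_chains_with_different_seeds_agree(self):
        rng = np.random.default_rng(14)
        n, m = 300, 40
        M = rng.binomial(2, 0.4, (n, m)).astype(float)
        beta = np.zeros(m)
        beta[[3, 20, 33]] = [1.0, -0.8, 0.6]
        y = M @ beta + rng.standard_normal(n)
        fits = [bs.bayesc(M, y, pi=0.9, chain_length=2000, burn_in=500,
                          vg=float(np.var(M @ beta)), ve=1.0,
                          rng=np.random.default_rng(s)) for s in (1, 2)]
        r = np.corrcoef(fits[0]["ebv"], fits[1]["ebv"])[0, 1]
        assert r > 0.95

    def test_invalid_chain_settings_rejected(self):
        with pytest.raises(ValidationError):
            bs.bayesc(np.zeros((3, 2)), np.zeros(3), chain_length=10,
                      burn_in=10)


class TestSelection:
    def test_weighted_index_selection_matches_brute_force(self):
        genome = bs.build_genome(n_chr=1, n_loci=50)
        phenome = bs.build_phenome(genome, [10, 20], vg=[1.0, 1.0],
                                   h2=[0.5, 0.5], seed=15)
        sim = bs.Simulation(genome, phenome, seed=15)
        A = sim.founders(100)
        chosen = bs.select(A, 50, criteria="EBV", methods="GBLUP",
                           weights=[3.0, -2.0])
        scores = A.get_EBVs() @ np.array([3.0, -2.0])
        expected = set(A.ids[np.argsort(-scores)][:50])
        assert set(chosen.ids) == expected

    def test_negative_weight_selects_lowest_phenotypes(self):
        sim = make_sim(seed=16)
        A = sim.founders(30)
        low = bs.select(A, 5, criteria="phenotypes", weights=[-1.0])
        y = A.get_phenotypes()[:, 0]
        assert set(low.ids) == set(A.ids[np.argsort(y)][:5])

    def test_random_selection_is_uniform_subset(self):
        sim = make_sim(seed=17)
        A = sim.founders(20)
        S = bs.select(A, 7, criteria="random")
        assert S.n == 7 and len(set(S.ids)) == 7

    def test_selecting_more_than_available_rejected(self):
        sim = make_sim(seed=18)
        with pytest.raises(ValidationError):
            bs.select(sim.founders(3), 4)

    def test_mass_selection_improves_mean_breeding_value(self):
        wins = 0
        for rep in range(100):
            sim = make_sim(n_loci=50, n_qtl=10, h2=0.5, seed=500 + rep)
            A = sim.founders(1000)
            top = bs.select(A, 100, criteria="phenotypes")
            if top.get_BVs().mean() >= A.get_BVs().mean():
                wins += 1
        assert wins >= 95

    def test_breeders_equation_for_mass_selection(self):
        """R = h^2 S within 15% for truncation selection on a large cohort."""
        sim = make_sim(n_loci=100, n_qtl=30, h2=0.5, seed=19)
        A = sim.founders(5000)
        y = A.get_phenotypes()[:, 0]
        bv = A.get_BVs()[:, 0]
        top = bs.select(A, 1000, criteria="phenotypes")
        S = top.get_phenotypes()[:, 0].mean() - y.mean()
        R = top.get_BVs()[:, 0].mean() - bv.mean()
        h2_realized = bv.var() / y.var()
        assert abs(R - h2_realized * S) < 0.15 * h2_realized * S
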