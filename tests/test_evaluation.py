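"""Relationship matrices and GBLUP: tabular A vs gene dropping, VanRaden G,
single-step H vs a direct-formula oracle, and mixed-model closed forms."""

import numpy as np
import pytest

import bpsim
from bpsim.evaluation import gblup_solve, insert_ebv, pedigree_A, ssgblup_H, tabular_A, vanraden_G
from bpsim.meiosis import MeiosisParams, mate
from bpsim.population import PopulationError
from bpsim.traits import create_traits, observe_phenotypes
from helpers import gene_drop_A, random_pedigree, small_population

# a 7-individual pedigree with full sibs and a full-sib mating
PED = [(1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0),
       (5, 1, 2), (6, 1, 2), (7, 5, 6)]


class TestPedigreeA:
    def test_founders_are_identity(self, founder_pop):
        ids = founder_pop.generations[0][:5]
        np.testing.assert_allclose(pedigree_A(founder_pop, ids), np.eye(5))

    def test_textbook_entries(self):
        A, order = tabular_A(PED)
        pos = {i: k for k, i in enumerate(order)}
        assert A[pos[1], pos[5]] == pytest.approx(0.5)  # parent-offspring
        assert A[pos[5], pos[6]] == pytest.approx(0.5)  # full sibs
        assert A[pos[7], pos[7]] == pytest.approx(1.25)  # full-sib mating
        np.testing.assert_allclose(A, A.T)

    def test_matches_gene_dropping(self):
        A, order = tabular_A(PED)
        A_mc = gene_drop_A(PED, n_reps=100_000, seed=3)
        # binomial SE of the IBD estimates at 1e5 drops is below ~0.0035
        np.testing.assert_allclose(A_mc, A, atol=0.01)

    def test_population_pedigree_route(self):
        pop = small_population(n_indi=6, n_snp=50, seed=1)
        c1 = mate(pop, 1, 4, "M", "K", MeiosisParams(), np.random.default_rng(0))
        c2 = mate(pop, 1, 4, "F", "K", MeiosisParams(), np.random.default_rng(1))
        A = pedigree_A(pop, [c1.id, c2.id])
        assert A[0, 1] == pytest.approx(0.5)


class TestVanRadenG:
    def test_identical_individuals_have_equal_rows(self):
        M = np.array([[0, 0, 2], [1, 1, 0], [2, 2, 1]], dtype=float)
        G = vanraden_G(M, np.array([0.3, 0.4, 0.5]))
        np.testing.assert_allclose(G[0], G[1])
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_hand_computed_three_by_four(self):
        M = np.array([[0, 1, 2], [2, 1, 0], [1, 1, 1], [0, 0, 1]], dtype=float)
        p = np.array([0.25, 0.5, 0.5, 0.2])
        Z = M - 2 * p[:, None]
        expected = Z.T @ Z / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(vanraden_G(M, p), expected, atol=1e-12)

    def test_monomorphic_markers_dropped(self):
        M = np.array([[2, 2, 2], [0, 1, 2]], dtype=float)
        G = vanraden_G(M, np.array([1.0, 0.5]))
        expected = vanraden_G(M[1:], np.array([0.5]))
        np.testing.assert_allclose(G, expected)
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_G(M[:1], np.array([1.0]))

    def test_mean_diagonal_near_one_with_own_frequencies(self):
        pop = small_population(n_indi=500, n_snp=2000, n_chr=4, seed=9, freq=None)
        geno = bpsim.get_genotypes(pop, pop.generations[0])
        G = vanraden_G(geno, geno.mean(axis=1) / 2.0)
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.05)


class TestSingleStepH:
    def _pop(self):
        pop = small_population(n_indi=6, n_snp=400, n_chr=2, seed=21, freq=None)
        random_pedigree(pop, n_generations=2, per_gen=4, seed=5)
        return pop

    def test_none_genotyped_reduces_to_A(self):
        pop = self._pop()
        ids = sorted(pop.individuals)
        np.testing.assert_allclose(ssgblup_H(pop, [], ids), pedigree_A(pop, ids))

    def test_all_genotyped_is_adjusted_G_blend(self):
        pop = self._pop()
        ids = sorted(pop.individuals)
        H = ssgblup_H(pop, ids, ids, tau=1.0)
        A = pedigree_A(pop, ids)
        G = vanraden_G(bpsim.get_genotypes(pop, ids), pop.founder_allele_freqs())
        off = ~np.eye(len(ids), dtype=bool)
        coef = np.array([[np.mean(np.diag(G)), 1.0], [np.mean(G[off]), 1.0]])
        beta, alpha = np.linalg.solve(coef, [np.mean(np.diag(A)), np.mean(A[off])])
        np.testing.assert_allclose(H, beta * G + alpha, atol=1e-10)

    def test_mixed_case_matches_direct_inverse_formula(self):
        pop = self._pop()
        ids = sorted(pop.individuals)
        genotyped = ids[-4:]
        ng = [i for i in ids if i not in genotyped]
        order = ng + genotyped
        H = ssgblup_H(pop, genotyped, order, tau=0.95)
        # oracle: invert H^-1 = A^-1 + [[0,0],[0, Gt^-1 - A22^-1]]
        A = pedigree_A(pop, order)
        n1 = len(ng)
        A22 = A[n1:, n1:]
        G = vanraden_G(bpsim.get_genotypes(pop, genotyped), pop.founder_allele_freqs())
        off = ~np.eye(len(genotyped), dtype=bool)
        coef = np.array([[np.mean(np.diag(G)), 1.0], [np.mean(G[off]), 1.0]])
        beta, alpha = np.linalg.solve(coef, [np.mean(np.diag(A22)), np.mean(A22[off])])
        Gt = 0.95 * (beta * G + alpha) + 0.05 * A22
        Hinv = np.linalg.inv(A)
        Hinv[n1:, n1:] += np.linalg.inv(Gt) - np.linalg.inv(A22)
        np.testing.assert_allclose(H, np.linalg.inv(Hinv), atol=1e-8)
        assert np.min(np.linalg.eigvalsh(H)) > -1e-8

    def test_subset_violation_rejected(self):
        pop = self._pop()
        with pytest.raises(PopulationError):
            ssgblup_H(pop, [1, 2], [2, 3])


class TestGblupSolve:
    def test_identity_kinship_full_heritability_centers_phenotypes(self):
        y = np.array([1.0, 3.0, -2.0, 4.0])
        mu, g = gblup_solve(y, np.eye(4), h2=1.0)
        assert mu == pytest.approx(y.mean(), abs=1e-10)
        np.testing.assert_allclose(g, y - y.mean(), atol=1e-10)

    def test_identity_kinship_shrinks_by_h2(self):
        y = np.array([0.5, -1.0, 2.0, 1.5, -0.25])
        for h2 in (0.1, 0.5, 0.9):
            mu, g = gblup_solve(y, np.eye(5), h2=h2)
            np.testing.assert_allclose(g, h2 * (y - y.mean()), atol=1e-10)

    def test_ebv_variance_never_exceeds_phenotypic(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        for h2 in (0.2, 0.6, 1.0):
            _, g = gblup_solve(y, np.eye(30), h2=h2)
            assert np.var(g) <= np.var(y - y.mean()) + 1e-12

    def test_prediction_of_unphenotyped_relatives(self):
        K = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.0], [0.5, 0.0, 1.0]])
        y = np.array([2.0, -2.0, 0.0])
        mu, g = gblup_solve(y, K, h2=0.5, phenotyped=np.array([True, True, False]))
        assert g[2] != 0.0  # information flows through the relationship
        assert abs(g[2]) < abs(g[0])
        assert np.sign(g[2]) == np.sign(g[0])

    def test_empty_phenotype_set_rejected(self):
        with pytest.raises(ValueError):
            gblup_solve(np.array([1.0]), np.eye(1), 0.5, phenotyped=np.array([False]))

    def test_accuracy_increases_with_heritability(self):
        from scipy.stats import spearmanr

        h2_grid = [0.1, 0.3, 0.5, 0.7, 0.9]
        acc = {h2: [] for h2 in h2_grid}
        for rep in range(30):
            pop = small_population(n_indi=60, n_snp=300, n_chr=3, seed=100 + rep, freq=None)
            create_traits(pop.genome, pop, n_additive=20, var_target=1.0, seed=rep)
            ids = pop.generations[0]
            tbv = bpsim.compute_tbv(pop, ids)[0]
            G = vanraden_G(bpsim.get_genotypes(pop, ids), pop.founder_allele_freqs())
            for h2 in h2_grid:
                observe_phenotypes(pop, ids, heritability=h2, rng=np.random.default_rng(rep * 10 + int(h2 * 10)))
                y = np.array([pop.individuals[i].pheno[0] for i in ids])
                _, g = gblup_solve(y, G, h2=h2)
                acc[h2].append(np.corrcoef(g, tbv)[0, 1])
                for i in ids:  # reset records between heritability levels
                    pop.individuals[i].pheno = None
                    pop.individuals[i].pheno_n = None
        means = [np.mean(acc[h2]) for h2 in h2_grid]
        rho, _ = spearmanr(h2_grid, means)
        assert rho == pytest.approx(1.0)


class TestInsertEbv:
    def test_round_trip_and_selection_equivalence(self, founder_pop):
        create_traits(founder_pop.genome, founder_pop, n_additive=10, seed=0)
        ids = founder_pop.generations[0]
        tbv = bpsim.compute_tbv(founder_pop, ids)[0]
        insert_ebv(founder_pop, list(zip(ids, tbv)))
        got = np.array([founder_pop.individuals[i].ebv[0] for i in ids])
        np.testing.assert_allclose(got, tbv)
        top_ebv = bpsim.select_top(founder_pop, ids, "ebv", 5)
        top_tbv = bpsim.select_top(founder_pop, ids, "tbv", 5)
        assert top_ebv == top_tbv

    def test_unknown_ids_listed(self, founder_pop):
        with pytest.raises(PopulationError, match="999"):
            insert_ebv(founder_pop, [(999, 1.0)])
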