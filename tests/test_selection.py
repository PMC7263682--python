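"""Truncation selection, optimum genetic contributions, matings and the
breeding-action orchestrator."""

import numpy as np
import pytest
from scipy.optimize import minimize

import bpsim
from bpsim.evaluation import BLEND
from bpsim.population import PopulationError
from bpsim.selection import (
    BreedingActionConfig,
    breeding_action,
    compare_scenarios,
    ledger_total,
    make_matings,
    ogc_contributions,
    select_top,
)
from bpsim.traits import create_traits
from helpers import small_population


class TestSelectTop:
    def _with_tbv(self, values):
        pop = small_population(n_indi=len(values), n_snp=20, seed=1)
        for i, v in zip(pop.generations[0], values):
            bpsim.insert_ebv(pop, [(i, v)])
        return pop

    def test_whole_group_sorted_by_criterion(self):
        pop = self._with_tbv([1.0, 3.0, 2.0])
        assert select_top(pop, pop.generations[0], "ebv", 3) == [2, 3, 1]

    def test_top_n_by_value(self):
        pop = self._with_tbv([1.0, 3.0, 2.0])
        assert select_top(pop, pop.generations[0], "ebv", 2) == [2, 3]

    def test_ties_break_by_ascending_id(self):
        pop = self._with_tbv([5.0, 5.0, 5.0])
        assert select_top(pop, pop.generations[0], "ebv", 2) == [1, 2]

    def test_invariant_under_input_permutation(self):
        pop = self._with_tbv([0.5, -1.0, 2.0, 0.0])
        ids = pop.generations[0]
        ref = select_top(pop, ids, "ebv", 2)
        assert select_top(pop, ids[::-1], "ebv", 2) == ref

    def test_oversized_request_and_missing_values_rejected(self):
        pop = self._with_tbv([1.0, 2.0])
        with pytest.raises(PopulationError, match="cannot select"):
            select_top(pop, pop.generations[0], "ebv", 3)
        pop2 = small_population(n_indi=2, n_snp=20, seed=2)
        with pytest.raises(PopulationError, match="missing"):
            select_top(pop2, pop2.generations[0], "ebv", 1)


class TestOgc:
    def test_equal_ebvs_identity_kinship_gives_uniform_plan(self):
        sexes = ["M"] * 4 + ["F"] * 4
        plan = ogc_contributions(np.ones(8), np.eye(8), sexes, kinship_bound=0.5)
        np.testing.assert_allclose(plan.fractions, np.full(8, 0.125), atol=1e-10)

    def test_unbounded_kinship_concentrates_on_best(self):
        g = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        sexes = ["M", "M", "M", "F", "F", "F"]
        plan = ogc_contributions(g, np.eye(6), sexes, kinship_bound=np.inf)
        np.testing.assert_allclose(plan.fractions, [0, 0.5, 0, 0.5, 0, 0], atol=1e-10)

    def test_constraints_hold_exactly(self):
        rng = np.random.default_rng(4)
        L = rng.standard_normal((6, 6)) * 0.2
        K = np.eye(6) + L @ L.T
        g = rng.standard_normal(6)
        sexes = ["M", "F", "M", "F", "M", "F"]
        theta = 0.3
        plan = ogc_contributions(g, K, sexes, theta)
        c = plan.fractions
        male = np.array([s == "M" for s in sexes])
        assert c[male].sum() == pytest.approx(0.5, abs=1e-10)
        assert c[~male].sum() == pytest.approx(0.5, abs=1e-10)
        assert np.all(c >= -1e-12)
        Kb = (1 - BLEND) * K + BLEND * np.eye(6)
        assert c @ Kb @ c <= theta + 1e-8

    def test_matches_general_constrained_optimizer(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            L = rng.standard_normal((6, 6)) * 0.3
            K = np.eye(6) + L @ L.T
            g = rng.standard_normal(6)
            sexes = ["M", "F", "M", "F", "M", "F"]
            male = np.array([s == "M" for s in sexes])
            Kb = (1 - BLEND) * K + BLEND * np.eye(6)
            theta = 0.35
            plan = ogc_contributions(g, K, sexes, theta)
            res = minimize(
                lambda c: -c @ g,
                np.full(6, 0.25) * np.where(male, 1, 1),
                method="SLSQP",
                bounds=[(0, 0.5)] * 6,
                constraints=[
                    {"type": "eq", "fun": lambda c: c[male].sum() - 0.5},
                    {"type": "eq", "fun": lambda c: c[~male].sum() - 0.5},
                    {"type": "ineq", "fun": lambda c: theta - c @ Kb @ c},
                ],
                options={"ftol": 1e-12, "maxiter": 500},
            )
            assert res.success
            assert plan.fractions @ g == pytest.approx(-res.fun, abs=1e-6)

    def test_beats_equal_contribution_truncation(self):
        rng = np.random.default_rng(11)
        g = rng.standard_normal(8)
        sexes = ["M"] * 4 + ["F"] * 4
        K = np.eye(8)
        # equal contributions over the top 2 per sex: c'Kc = 4 * 0.25^2 = 0.25
        theta = 0.25
        plan = ogc_contributions(g, K, sexes, theta)
        male = np.array([s == "M" for s in sexes])
        trunc = np.zeros(8)
        for mask in (male, ~male):
            best2 = np.flatnonzero(mask)[np.argsort(-g[mask])[:2]]
            trunc[best2] = 0.25
        assert plan.fractions @ g >= trunc @ g - 1e-10

    def test_infeasible_bound_reports_minimum(self):
        with pytest.raises(PopulationError, match="minimum achievable"):
            ogc_contributions(np.ones(4), np.eye(4), ["M", "M", "F", "F"], kinship_bound=0.01)


class TestMatings:
    def test_single_pair_repeated(self):
        assert make_matings([7], [9], 3, rng=np.random.default_rng(0)) == [(7, 9)] * 3

    def test_share_a_sire_probability(self):
        rng = np.random.default_rng(1)
        pairs = make_matings(list(range(20)), list(range(100, 120)), 100_000, rng=rng)
        sires = np.array([p[0] for p in pairs])
        share = np.mean(sires[0::2] == sires[1::2])
        assert share == pytest.approx(0.05, abs=0.003)

    def test_balanced_follows_contributions(self):
        pairs = make_matings(
            [1, 2], [3, 4], 10, scheme="balanced",
            contributions={1: 0.5, 2: 0.0, 3: 0.25, 4: 0.25},
            rng=np.random.default_rng(2),
        )
        assert all(s == 1 for s, _ in pairs)
        dams = [d for _, d in pairs]
        assert dams.count(3) == 5 and dams.count(4) == 5


class TestBreedingAction:
    def _founder_pop(self, seed=3):
        pop = small_population(n_indi=30, n_snp=400, n_chr=2, seed=seed, freq=None)
        create_traits(pop.genome, pop, n_additive=15, var_target=1.0, seed=1)
        return pop

    def _action(self, **kw):
        base = dict(
            name="Offspring",
            phenotyping={"heritability": 0.5},
            evaluation={"kind": "G", "h2": 0.5},
            breeding_size=20,
            selection_size=(5, 5),
            selection_criterion="bve",
            selection_m={"cohorts": ["Founder_M"]},
            selection_f={"cohorts": ["Founder_F"]},
        )
        base.update(kw)
        return BreedingActionConfig(**base)

    def test_offspring_cohorts_and_generation(self):
        pop = self._founder_pop()
        breeding_action(pop, self._action())
        assert pop.n_generations == 2
        assert len(pop.generations[1]) == 20
        assert set(pop.cohorts) == {"Founder_M", "Founder_F", "Offspring_M", "Offspring_F"}
        assert len(pop.cohorts["Offspring_M"].ids) == 10

    def test_zero_breeding_size_only_books_costs(self):
        pop = self._founder_pop()
        before = len(pop.individuals)
        breeding_action(pop, BreedingActionConfig(name="Nothing", costs={"fixed": 50.0}))
        assert len(pop.individuals) == before
        assert pop.n_generations == 1
        assert ledger_total(pop) == 50.0

    def test_joint_action_equals_split_actions(self):
        joint = self._founder_pop(seed=9)
        breeding_action(joint, self._action())
        split = self._founder_pop(seed=9)
        breeding_action(split, BreedingActionConfig(name="P", phenotyping={"heritability": 0.5}))
        breeding_action(split, BreedingActionConfig(name="E", evaluation={"kind": "G", "h2": 0.5}))
        breeding_action(split, self._action(phenotyping=None, evaluation=None))
        ids = sorted(joint.individuals)
        assert ids == sorted(split.individuals)
        np.testing.assert_array_equal(
            bpsim.get_genotypes(joint, ids), bpsim.get_genotypes(split, ids)
        )

    def test_ogc_action_runs(self):
        pop = self._founder_pop(seed=12)
        breeding_action(pop, self._action(selection_method="ogc", ogc_theta=0.05,
                                          selection_size=None, mating_scheme="balanced"))
        assert len(pop.generations[1]) == 20


class TestLedger:
    def test_costs_accumulate(self):
        pop = small_population(n_indi=10, n_snp=50, seed=1)
        create_traits(pop.genome, pop, n_additive=5, seed=2)
        assert ledger_total(pop) == 0.0
        breeding_action(pop, BreedingActionConfig(
            name="A", phenotyping={"heritability": 0.5}, costs={"phenotyping": 10.0}))
        breeding_action(pop, BreedingActionConfig(name="B", costs={"fixed": 50.0}))
        assert ledger_total(pop) == 10.0 * 10 + 50.0

    def test_compare_scenarios_table(self):
        res = {
            "low": {"aggregate": {"mean_tbv_by_generation": [0.0, 0.6],
                                  "mean_kinship_by_generation": [0.0, 0.006],
                                  "total_cost": 100.0}},
            "high": {"aggregate": {"mean_tbv_by_generation": [0.0, 0.9],
                                   "mean_kinship_by_generation": [0.0, 0.016],
                                   "total_cost": 100.0}},
        }
        table = compare_scenarios(res, gain_value=1000.0)
        assert table.loc["high", "gain"] > table.loc["low", "gain"]
        assert table.loc["high", "kinship_change"] > table.loc["low", "kinship_change"]
        assert table.loc["high", "revenue"] == pytest.approx(0.9 * 1000 - 100)
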