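"""Selection, mating-pair generation, and the breeding-action orchestrator.

A breeding action bundles the steps a breeder performs on a group of
candidates: phenotype them, run a genetic evaluation, select parents per sex
(truncation on a criterion, or optimum genetic contributions under a kinship
constraint), mate them, and book the costs. Steps are optional and can be run
in separate actions or one joint action with identical results, because each
stochastic sub-step draws from its own named RNG stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import BLEND, gblup_solve, pedigree_A, ssgblup_H, vanraden_G
from .meiosis import MeiosisParams, mate
from .population import Population, PopulationError, get_genotypes, resolve_group
from .traits import compute_tbv, observe_phenotypes

__all__ = [
    "BreedingActionConfig",
    "ContributionPlan",
    "select_top",
    "ogc_contributions",
    "make_matings",
    "breeding_action",
    "ledger_total",
    "compare_scenarios",
]


@dataclass
class BreedingActionConfig:
    """Declarative description of one breeding action.

    Group selectors are dicts with any of the keys ``gen``, ``cohorts``,
    ``database`` (see :func:`bpsim.population.resolve_group`); ``None`` means
    the last generation.
    """

    name: str = "Offspring"
    # phenotyping
    phenotyping: dict | None = None  # {"heritability": .., "groups": sel, "n_obs": 1}
    # evaluation
    evaluation: dict | None = None  # {"kind": "G"|"A"|"H", "h2": .., "groups": sel, "genotyped": sel}
    # selection + reproduction
    breeding_size: int = 0
    selection_size: tuple[int, int] | None = None
    selection_criterion: str = "random"  # ebv|bve|pheno|tbv|random
    selection_m: dict | None = None
    selection_f: dict | None = None
    selection_method: str = "truncation"  # or "ogc"
    ogc_theta: float | None = None
    trait_weights: Sequence[float] | None = None
    mating_scheme: str = "random_with_replacement"  # or "balanced"
    sex_ratio: float = 0.5
    mutation_rate: float = 0.0
    # economics: unit costs per counted item
    costs: dict = field(default_factory=dict)  # keys: phenotyping, evaluation, offspring, fixed


@dataclass
class ContributionPlan:
    ids: list[int]
    fractions: np.ndarray  # c >= 0, sums to 0.5 per sex
    achieved: float  # c' K* c on the blended matrix the program was solved on

    def as_dict(self) -> dict[int, float]:
        return {i: float(c) for i, c in zip(self.ids, self.fractions)}


def _criterion_values(pop: Population, ids, criterion: str, weights) -> np.ndarray:
    arch = pop.traits
    nt = 1 if arch is None else arch.n_traits
    w = np.ones(nt) if weights is None else np.asarray(weights, dtype=float)
    vals = np.empty(len(ids))
    missing = []
    for j, iid in enumerate(ids):
        ind = pop.individuals[iid]
        if criterion in ("ebv", "bve"):
            v = ind.ebv
        elif criterion == "pheno":
            v = ind.pheno
        elif criterion == "tbv":
            if ind.tbv is None:
                compute_tbv(pop, [iid])
            v = ind.tbv
        else:
            raise ValueError(f"unknown selection criterion {criterion!r}")
        if v is None:
            missing.append(iid)
        else:
            vals[j] = float(np.dot(w, v))
    if missing:
        raise PopulationError(f"criterion {criterion!r} missing for individuals {missing}")
    return vals


def select_top(
    pop: Population,
    group: Sequence[int],
    criterion: str,
    n: int,
    trait_weights: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Ids of the ``n`` best candidates by the weighted selection index.

    Ties break by ascending id; the result does not depend on the input order
    of ``group``. ``criterion="random"`` draws a seeded permutation.
    """
    ids = sorted(set(group))
    if n > len(ids):
        raise PopulationError(f"cannot select {n} from a group of {len(ids)}")
    if criterion == "random":
        rng = rng if rng is not None else pop.hub["selection"]
        perm = rng.permutation(len(ids))
        return [ids[k] for k in perm[:n]]
    vals = _criterion_values(pop, ids, criterion, trait_weights)
    order = sorted(range(len(ids)), key=lambda k: (-vals[k], ids[k]))
    return [ids[k] for k in order[:n]]


def ogc_contributions(
    ebv: np.ndarray,
    K: np.ndarray,
    sexes: Sequence[str],
    kinship_bound: float,
    ids: Sequence[int] | None = None,
) -> ContributionPlan:
    """Optimum genetic contributions under an average-relationship constraint.

    Maximizes c'g subject to c'K*c <= theta, per-sex sums of 0.5 and c >= 0,
    where K* = 0.99 K + 0.01 I is the blended relationship matrix the whole
    program is defined on. Solved in Lagrangian form c = K*^{-1}(g - Q l0) /
    (2 lambda) with iterative truncation of negative contributions
    (re-solving on the active set). ``theta = inf`` degenerates to all mass
    on the best candidate of each sex.
    """
    g = np.asarray(ebv, dtype=float)
    n = g.size
    sexes = list(sexes)
    ids = list(ids) if ids is not None else list(range(n))
    male = np.array([s == "M" for s in sexes])
    if not male.any() or male.all():
        raise PopulationError("OGC needs candidates of both sexes")
    Kb = (1.0 - BLEND) * np.asarray(K, dtype=float) + BLEND * np.eye(n)
    c = np.zeros(n)

    if not np.isfinite(kinship_bound):
        for mask in (male, ~male):
            sub = np.flatnonzero(mask)
            best = sub[np.lexsort((np.asarray(ids)[sub], -g[sub]))[0]]
            c[best] = 0.5
        return ContributionPlan(ids, c, float(c @ Kb @ c))

    active = np.arange(n)
    s = np.array([0.5, 0.5])
    for _ in range(n + 1):
        KA = Kb[np.ix_(active, active)]
        gA = g[active]
        Q = np.stack([male[active].astype(float), (~male[active]).astype(float)], axis=1)
        if np.any(Q.sum(axis=0) == 0):
            raise PopulationError("OGC truncation removed all candidates of one sex")
        Ki = np.linalg.inv(KA)
        QtKiQ = Q.T @ Ki @ Q
        W = np.linalg.inv(QtKiQ)
        B0 = float(s @ W @ s)  # minimum achievable c'K*c on this active set
        if kinship_bound < B0 - 1e-12:
            raise PopulationError(
                f"kinship bound {kinship_bound} infeasible; minimum achievable c'Kc is {B0:.6g}"
            )
        proj = Ki - Ki @ Q @ W @ Q.T @ Ki
        A0 = float(gA @ proj @ gA)
        if A0 <= 1e-14 or kinship_bound <= B0 + 1e-14:
            cA = Ki @ Q @ W @ s
        else:
            twolam = np.sqrt(A0 / (kinship_bound - B0))
            l0 = W @ (Q.T @ Ki @ gA - twolam * s)
            cA = Ki @ (gA - Q @ l0) / twolam
        if cA.min() >= -1e-12:
            c = np.zeros(n)
            c[active] = np.clip(cA, 0.0, None)
            return ContributionPlan(ids, c, float(c @ Kb @ c))
        active = active[cA > 1e-12]
    raise PopulationError("OGC active-set iteration failed to converge")


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    quota = w / w.sum() * total
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    if rem > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:rem]] += 1
    return counts


def make_matings(
    sires: Sequence[int],
    dams: Sequence[int],
    n_offspring: int,
    scheme: str = "random_with_replacement",
    contributions: dict[int, float] | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Generate ``n_offspring`` (sire, dam) pairs.

    ``random_with_replacement`` draws each pair uniformly and independently.
    ``balanced`` assigns per-parent usage counts proportional to
    ``contributions`` (uniform if absent) by largest-remainder rounding, then
    pairs the resulting lists in random order.
    """
    if not sires or not dams:
        raise PopulationError("need at least one sire and one dam")
    rng = rng if rng is not None else np.random.default_rng()
    sires, dams = list(sires), list(dams)
    if scheme == "random_with_replacement":
        si = rng.integers(0, len(sires), size=n_offspring)
        di = rng.integers(0, len(dams), size=n_offspring)
        return [(sires[a], dams[b]) for a, b in zip(si, di)]
    if scheme == "balanced":
        out = []
        for parents in (sires, dams):
            w = (
                np.array([contributions.get(p, 0.0) for p in parents])
                if contributions
                else np.ones(len(parents))
            )
            counts = _largest_remainder(w, n_offspring)
            lst = np.repeat(np.asarray(parents), counts)
            out.append(rng.permutation(lst))
        return list(zip(out[0].tolist(), out[1].tolist()))
    raise ValueError(f"unknown mating scheme {scheme!r}")


def _resolve(pop: Population, sel: dict | None) -> list[int]:
    sel = sel or {}
    return resolve_group(pop, gen=sel.get("gen"), cohorts=sel.get("cohorts"), database=sel.get("database"))


def run_evaluation(pop: Population, evaluation: dict) -> list[int]:
    """Run a genetic evaluation and store EBVs on the candidates."""
    kind = evaluation.get("kind", "G")
    h2 = evaluation["h2"]
    ids = _resolve(pop, evaluation.get("groups"))
    if kind == "G":
        K = vanraden_G(get_genotypes(pop, ids), pop.founder_allele_freqs())
    elif kind == "A":
        K = pedigree_A(pop, ids)
    elif kind == "H":
        genotyped = _resolve(pop, evaluation["genotyped"]) if evaluation.get("genotyped") else ids
        K = ssgblup_H(pop, genotyped, ids)
    else:
        raise ValueError(f"unknown relationship kind {kind!r}")
    arch = pop.traits
    nt = 1 if arch is None else arch.n_traits
    h2v = np.broadcast_to(np.atleast_1d(np.asarray(h2, dtype=float)), (nt,))
    pmask = np.array([pop.individuals[i].pheno is not None for i in ids])
    if not pmask.any():
        raise PopulationError("evaluation requested but no candidate has phenotypes")
    for t in range(nt):
        y = np.array([
            pop.individuals[i].pheno[t] if pop.individuals[i].pheno is not None else np.nan
            for i in ids
        ])
        nobs = np.array([
            pop.individuals[i].pheno_n[t] if pop.individuals[i].pheno_n is not None else 1
            for i in ids
        ])[pmask]
        _, gvec = gblup_solve(np.nan_to_num(y), K, float(h2v[t]), phenotyped=pmask, n_obs=nobs)
        for j, iid in enumerate(ids):
            ind = pop.individuals[iid]
            if ind.ebv is None:
                ind.ebv = np.zeros(nt)
            ind.ebv[t] = gvec[j]
    return ids


def breeding_action(pop: Population, config: BreedingActionConfig) -> Population:
    """Execute one breeding action: phenotyping -> evaluation -> selection ->
    matings -> offspring cohorts -> cost ledger. Omitted sub-steps are
    skipped; empty group selectors default to the last generation."""
    counted: dict[str, int] = {}
    try:
        if config.phenotyping is not None:
            ph = config.phenotyping
            ids = _resolve(pop, ph.get("groups"))
            observe_phenotypes(pop, ids, ph["heritability"], n_obs=ph.get("n_obs", 1))
            counted["phenotyping"] = len(ids)
        if config.evaluation is not None:
            ids = run_evaluation(pop, config.evaluation)
            counted["evaluation"] = len(ids)
        if config.breeding_size > 0:
            sel_rng = pop.hub["selection"]
            cand_m = [i for i in _resolve(pop, config.selection_m) if pop.individuals[i].sex == "M"]
            cand_f = [i for i in _resolve(pop, config.selection_f) if pop.individuals[i].sex == "F"]
            contributions = None
            if config.selection_method == "ogc":
                cand = sorted(set(cand_m) | set(cand_f))
                g = _criterion_values(pop, cand, config.selection_criterion, config.trait_weights)
                K = vanraden_G(get_genotypes(pop, cand), pop.founder_allele_freqs())
                plan = ogc_contributions(
                    g, K, [pop.individuals[i].sex for i in cand],
                    config.ogc_theta if config.ogc_theta is not None else np.inf, ids=cand,
                )
                contributions = plan.as_dict()
                sires = [i for i in cand if pop.individuals[i].sex == "M" and contributions[i] > 0]
                dams = [i for i in cand if pop.individuals[i].sex == "F" and contributions[i] > 0]
                scheme = "balanced"
            else:
                n_m, n_f = config.selection_size if config.selection_size else (len(cand_m), len(cand_f))
                sires = select_top(pop, cand_m, config.selection_criterion, n_m, config.trait_weights, sel_rng)
                dams = select_top(pop, cand_f, config.selection_criterion, n_f, config.trait_weights, sel_rng)
                scheme = config.mating_scheme
            pairs = make_matings(
                sires, dams, config.breeding_size, scheme, contributions, rng=sel_rng
            )
            params = MeiosisParams(mutation_rate=config.mutation_rate)
            generation = pop.n_generations + 1
            mei_rng = pop.hub["meiosis"]
            n_total = config.breeding_size
            n_male = int(np.ceil(n_total * config.sex_ratio - 1e-9))
            alternating = n_male == (n_total + 1) // 2
            new_ids = []
            for k, (s, d) in enumerate(pairs):
                # deterministic floor/ceil sex counts; alternate at a 50/50 ratio
                sex = ("M" if k % 2 == 0 else "F") if alternating else ("M" if k < n_male else "F")
                child = mate(pop, s, d, sex, f"{config.name}_{sex}", params, mei_rng, generation)
                new_ids.append(child.id)
            if pop.traits is not None and pop.traits.has_qtl():
                compute_tbv(pop, new_ids)
            counted["offspring"] = len(new_ids)
        counted["fixed"] = 1 if "fixed" in config.costs else 0
        for item, cnt in counted.items():
            unit = float(config.costs.get(item, 0.0))
            pop.ledger.append({
                "action": config.name, "item": item, "count": cnt,
                "unit_cost": unit, "total": unit * cnt,
            })
    except PopulationError as err:
        raise PopulationError(f"breeding action {config.name!r}: {err}") from err
    return pop


def ledger_total(pop: Population) -> float:
    """Accumulated cost of all booked breeding actions."""
    return float(sum(entry["total"] for entry in pop.ledger))


def compare_scenarios(results: dict[str, dict], gain_value: float = 0.0) -> pd.DataFrame:
    """Tabulate scenario outcomes: cost, genetic gain, kinship change and
    revenue = gain * gain_value - cost.

    ``results`` maps scenario name to a :func:`bpsim.scenario.run_scenario`
    bundle (its ``aggregate`` part is used).
    """
    rows = []
    for name, res in results.items():
        agg = res.get("aggregate", res)
        tbv = agg.get("mean_tbv_by_generation", [])
        kin = agg.get("mean_kinship_by_generation", [])
        gain = (tbv[-1] - tbv[0]) if len(tbv) >= 2 else np.nan
        dk = (kin[-1] - kin[0]) if len(kin) >= 2 else np.nan
        cost = agg.get("total_cost", 0.0)
        rows.append({
            "scenario": name, "total_cost": cost, "gain": gain,
            "kinship_change": dk, "revenue": gain * gain_value - cost,
            "mean_tbv_by_generation": tbv,
        })
    return pd.DataFrame(rows).set_index("scenario")
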