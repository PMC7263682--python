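"""Declarative scenario execution: build a founder population, run an ordered
list of breeding actions, replicate with offset seeds, aggregate.

A scenario is a JSON-serializable dict::

    {
      "seed": 1, "replicates": 10,
      "genome": {"n_chr": 5, "chr_length_morgan": 2.0, "n_snp": 10000},
      "founders": {"n": 100, "sex_ratio": 0.5, "cohort": "Founder", "freq": null},
      "traits": {"n_additive": 50, "n_dominant": 10, "var_target": 1.0},
      "actions": [ { ...BreedingActionConfig fields... } ]
    }

Replicate ``r`` runs with seed ``seed + r``; all randomness inside a replicate
flows from that one seed through named streams, so outputs are fully
deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import group_mean_coancestry
from .genome import build_genome
from .population import Population, create_founder_population
from .selection import BreedingActionConfig, breeding_action, ledger_total
from .traits import compute_tbv

__all__ = ["validate_config", "run_scenario", "run_replicate", "save_population", "load_population"]

logger = logging.getLogger("bpsim")

SNAPSHOT_MAGIC = "bpsim.population"
SNAPSHOT_VERSION = 1

_ACTION_FIELDS = {f.name for f in dataclasses.fields(BreedingActionConfig)}


def validate_config(config: dict) -> list[str]:
    """Pure schema check; returns human-readable violations with JSON paths."""
    v: list[str] = []
    if not isinstance(config, dict):
        return ["$: config must be an object"]
    if "seed" not in config:
        v.append("$.seed: missing master seed")
    elif not isinstance(config["seed"], int):
        v.append("$.seed: must be an integer")
    reps = config.get("replicates", 1)
    if not (isinstance(reps, int) and reps >= 1):
        v.append("$.replicates: must be a positive integer")
    g = config.get("genome")
    if not isinstance(g, dict):
        v.append("$.genome: missing genome spec")
    else:
        for key in ("n_chr", "n_snp"):
            if not (isinstance(g.get(key), int) and g[key] >= 1):
                v.append(f"$.genome.{key}: must be an integer >= 1")
        if not (isinstance(g.get("chr_length_morgan"), (int, float)) and g.get("chr_length_morgan", 0) > 0):
            v.append("$.genome.chr_length_morgan: must be > 0")
    f = config.get("founders")
    n_founders = None
    if not isinstance(f, dict) or not (isinstance(f.get("n"), int) and f["n"] >= 1):
        v.append("$.founders.n: must be an integer >= 1")
    else:
        n_founders = f["n"]
    t = config.get("traits")
    if t is not None and isinstance(t, dict) and isinstance(g, dict) and isinstance(g.get("n_snp"), int):
        if t.get("n_additive", 0) + t.get("n_dominant", 0) > g["n_snp"]:
            v.append("$.traits: more QTL than markers")
    for k, action in enumerate(config.get("actions", [])):
        path = f"$.actions[{k}]"
        unknown = set(action) - _ACTION_FIELDS
        if unknown:
            v.append(f"{path}: unknown fields {sorted(unknown)}")
        size = action.get("selection_size")
        if size is not None:
            if len(size) != 2 or any(s < 0 for s in size):
                v.append(f"{path}.selection_size: must be two non-negative sizes")
            elif n_founders is not None and action.get("selection_m") is None and sum(size) > n_founders:
                v.append(f"{path}.selection_size: exceeds candidate group size {n_founders}")
        if action.get("breeding_size", 0) < 0:
            v.append(f"{path}.breeding_size: must be >= 0")
    return v


def _build_population(config: dict, seed: int) -> Population:
    g = config["genome"]
    genome = build_genome(g["n_chr"], g["chr_length_morgan"], g["n_snp"])
    f = config.get("founders", {})
    freq = f.get("freq")
    trait_spec = dict(config["traits"]) if config.get("traits") else None
    return create_founder_population(
        genome,
        f.get("n", 100),
        cohort_name=f.get("cohort", "Founder"),
        sex_ratio=f.get("sex_ratio", 0.5),
        seed=seed,
        freq_spec=None if freq in (None, "runif") else freq,
        trait_spec=trait_spec,
    )


def run_replicate(config: dict, seed: int) -> tuple[Population, dict]:
    """Run one replicate and return (population, flat summary row)."""
    pop = _build_population(config, seed)
    for action in config.get("actions", []):
        cfg = BreedingActionConfig(**action)
        breeding_action(pop, cfg)
        logger.info(
            "action %s: breeding_size=%d criterion=%s cost=%.2f",
            cfg.name, cfg.breeding_size, cfg.selection_criterion,
            sum(e["total"] for e in pop.ledger if e["action"] == cfg.name),
        )
    row: dict = {"seed": seed, "total_cost": ledger_total(pop)}
    for g in range(pop.n_generations):
        ids = pop.generations[g]
        if pop.traits is not None and pop.traits.has_qtl():
            row[f"mean_tbv_gen{g + 1}"] = float(compute_tbv(pop, ids).mean())
        if len(ids) >= 2:
            row[f"mean_kinship_gen{g + 1}"] = group_mean_coancestry(pop, ids) / 2.0
    return pop, row


def run_scenario(config: dict, reps: int | None = None, seed: int | None = None, out_dir=None) -> dict:
    """Run all replicates of a scenario and aggregate.

    Returns ``{"replicates": DataFrame, "aggregate": dict, "population":
    last replicate's Population}``. The aggregate holds the mean and standard
    error of every per-replicate summary plus per-generation trajectories.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid scenario config:\n" + "\n".join(violations))
    reps = reps if reps is not None else config.get("replicates", 1)
    seed = seed if seed is not None else config["seed"]
    rows = []
    pop = None
    for r in range(reps):
        pop, row = run_replicate(config, seed + r)
        row["replicate"] = r
        rows.append(row)
    df = pd.DataFrame(rows).set_index("replicate")
    agg: dict = {"n_replicates": reps, "seed": seed}
    for col in df.columns:
        if col == "seed":
            continue
        vals = df[col].dropna().to_numpy(dtype=float)
        agg[f"{col}_mean"] = float(vals.mean())
        agg[f"{col}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    n_gen = pop.n_generations if pop is not None else 0
    agg["mean_tbv_by_generation"] = [
        agg.get(f"mean_tbv_gen{g + 1}_mean", float("nan")) for g in range(n_gen)
    ]
    agg["mean_kinship_by_generation"] = [
        agg.get(f"mean_kinship_gen{g + 1}_mean", float("nan")) for g in range(n_gen)
    ]
    agg["total_cost"] = agg.get("total_cost_mean", 0.0)
    if n_gen >= 2 and not np.isnan(agg["mean_tbv_by_generation"][-1]):
        agg["gain"] = agg["mean_tbv_by_generation"][-1] - agg["mean_tbv_by_generation"][0]
        agg["kinship_increase"] = (
            agg["mean_kinship_by_generation"][-1] - agg["mean_kinship_by_generation"][0]
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "replicates.csv")
        with open(out / "aggregate.json", "w") as fh:
            json.dump(agg, fh, indent=1)
        if pop is not None:
            save_population(pop, out / "population.pop")
    return {"replicates": df, "aggregate": agg, "population": pop}


def save_population(pop: Population, path) -> None:
    """Versioned binary population snapshot (pickle container)."""
    with open(path, "wb") as fh:
        pickle.dump({"magic": SNAPSHOT_MAGIC, "version": SNAPSHOT_VERSION, "population": pop}, fh)


def load_population(path) -> Population:
    with open(path, "rb") as fh:
        obj = pickle.load(fh)
    if not isinstance(obj, dict) or obj.get("magic") != SNAPSHOT_MAGIC:
        raise ValueError(f"{path} is not a bpsim population snapshot")
    if obj.get("version") != SNAPSHOT_VERSION:
        raise ValueError(f"unsupported snapshot version {obj.get('version')}")
    return obj["population"]
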