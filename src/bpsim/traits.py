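"""Genetic trait architectures: QTL effects, true breeding values, phenotypes.

A trait is defined by additive, dominant and epistatic QTL placed on existing
markers. After sampling, effects are affine-rescaled on the realized founder
cohort so founder TBV has mean exactly 0 and variance exactly ``var_target``
per trait — genetic gain is then directly in founder genomic standard
deviations. Multiple traits can share QTL pleiotropically with a target
genetic correlation, imposed by drawing each QTL's per-trait effect vector
from N(0, C) via a Cholesky root of the correlation matrix C.

Phenotypes are single observations y = TBV + e with e ~ N(0, sigma_e^2),
sigma_e^2 = var_target * (1 - h2) / h2; repeated observations are averaged
and stored with their count (effective residual variance sigma_e^2 / n).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genome import Genome
from .population import Population, get_genotypes
from .rng import as_rng

__all__ = [
    "QTL",
    "EpistaticTerm",
    "TraitArchitecture",
    "create_traits",
    "compute_tbv",
    "observe_phenotypes",
]


@dataclass
class QTL:
    marker: int  # global marker index, 0-based
    values: np.ndarray  # (n_traits, 3) effect for dosage 0/1/2

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))


@dataclass
class EpistaticTerm:
    markers: tuple[int, int]
    grid: np.ndarray  # (n_traits, 3, 3) value over joint dosages

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim == 2:
            self.grid = self.grid[None, :, :]
        if self.markers[0] == self.markers[1]:
            raise ValueError("epistatic term needs distinct markers")


@dataclass
class TraitArchitecture:
    trait_names: list[str]
    qtl: list[QTL] = field(default_factory=list)
    epistatic: list[EpistaticTerm] = field(default_factory=list)
    var_target: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    gen_corr: np.ndarray | None = None
    center: np.ndarray | None = None  # per-trait constant subtracted from raw sums

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def all_markers(self) -> np.ndarray:
        mk = [q.marker for q in self.qtl]
        for t in self.epistatic:
            mk.extend(t.markers)
        return np.unique(np.asarray(mk, dtype=np.int64))

    def has_qtl(self) -> bool:
        return bool(self.qtl or self.epistatic)

    # -- raw genetic values ------------------------------------------------
    def raw_values(self, dosages: np.ndarray, marker_index: dict[int, int]) -> np.ndarray:
        """Unscaled genetic values (n_traits x n) from a dosage submatrix whose
        rows are indexed by ``marker_index`` (global marker -> row)."""
        n = dosages.shape[1]
        out = np.zeros((self.n_traits, n))
        for q in self.qtl:
            d = dosages[marker_index[q.marker]]
            out += q.values[:, d]
        for t in self.epistatic:
            d1 = dosages[marker_index[t.markers[0]]]
            d2 = dosages[marker_index[t.markers[1]]]
            out += t.grid[:, d1, d2]
        return out

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        obj = {
            "trait_names": self.trait_names,
            "var_target": self.var_target.tolist(),
            "gen_corr": None if self.gen_corr is None else self.gen_corr.tolist(),
            "center": None if self.center is None else self.center.tolist(),
            "qtl": [{"marker": q.marker + 1, "values": q.values.tolist()} for q in self.qtl],
            "epistatic": [
                {"markers": [m + 1 for m in t.markers], "grid": t.grid.tolist()}
                for t in self.epistatic
            ],
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "TraitArchitecture":
        try:
            obj = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                obj = json.load(fh)
        return cls(
            trait_names=obj["trait_names"],
            qtl=[QTL(q["marker"] - 1, np.array(q["values"])) for q in obj["qtl"]],
            epistatic=[
                EpistaticTerm(tuple(m - 1 for m in t["markers"]), np.array(t["grid"]))
                for t in obj["epistatic"]
            ],
            var_target=np.array(obj["var_target"]),
            gen_corr=None if obj["gen_corr"] is None else np.array(obj["gen_corr"]),
            center=None if obj["center"] is None else np.array(obj["center"]),
        )


def _founder_dosages(founders, markers: np.ndarray) -> np.ndarray:
    if isinstance(founders, Population):
        ids = founders.generations[0]
        return get_genotypes(founders, ids, markers=markers)
    dosages = np.asarray(founders)
    return dosages[markers]


def create_traits(
    genome: Genome,
    founders,
    n_additive: int = 0,
    n_dominant: int = 0,
    epistatic_spec=None,
    n_traits: int = 1,
    gen_corr: np.ndarray | None = None,
    var_target=1.0,
    seed=None,
    dominance_degree: float = 1.0,
    trait_names: list[str] | None = None,
) -> TraitArchitecture:
    """Sample a QTL architecture and scale it on the founder cohort.

    Additive QTL get genotype values (0, a, 2a) with a ~ N(0, 1); dominant QTL
    get (0, d, a) with d = dominance_degree * a (complete dominance by
    default). ``epistatic_spec`` is either an integer count of random pairwise
    3x3 interaction grids (entries N(0, 1)) or an explicit list of
    ``(markers, grid)`` pairs. ``founders`` is a Population (its generation 1
    is the scaling reference) or a full dosage matrix; effects are rescaled so
    founder TBV has mean 0 and variance ``var_target`` exactly.
    """
    rng = as_rng(seed)
    var_target = np.broadcast_to(np.atleast_1d(np.asarray(var_target, dtype=float)), (n_traits,)).copy()
    if trait_names is None:
        trait_names = [f"Trait {t + 1}" for t in range(n_traits)]
    if gen_corr is None:
        gen_corr = np.eye(n_traits)
    gen_corr = np.asarray(gen_corr, dtype=float)
    if gen_corr.shape != (n_traits, n_traits) or not np.allclose(gen_corr, gen_corr.T):
        raise ValueError("gen_corr must be a symmetric n_traits x n_traits matrix")
    w, _ = np.linalg.eigh(gen_corr)
    if np.min(w) < -1e-10 or not np.allclose(np.diag(gen_corr), 1.0):
        raise ValueError("gen_corr must be positive semi-definite with unit diagonal")
    chol = np.linalg.cholesky(gen_corr + 1e-12 * np.eye(n_traits))

    n_qtl = n_additive + n_dominant
    if n_qtl > genome.total_snps:
        raise ValueError(f"requested {n_qtl} QTL but genome has {genome.total_snps} markers")
    markers = rng.choice(genome.total_snps, size=n_qtl, replace=False)

    qtl: list[QTL] = []
    for k in range(n_qtl):
        a = chol @ rng.standard_normal(n_traits)
        if k < n_additive:
            vals = np.stack([np.zeros(n_traits), a, 2 * a], axis=1)
        else:
            vals = np.stack([np.zeros(n_traits), dominance_degree * a, a], axis=1)
        qtl.append(QTL(int(markers[k]), vals))

    epistatic: list[EpistaticTerm] = []
    if isinstance(epistatic_spec, int):
        for _ in range(epistatic_spec):
            pair = tuple(int(x) for x in rng.choice(genome.total_snps, size=2, replace=False))
            grid = chol @ rng.standard_normal((n_traits, 9))
            epistatic.append(EpistaticTerm(pair, grid.reshape(n_traits, 3, 3)))
    elif epistatic_spec:
        for mk, grid in epistatic_spec:
            epistatic.append(EpistaticTerm(tuple(int(m) for m in mk), np.asarray(grid, dtype=float)))

    arch = TraitArchitecture(
        trait_names=trait_names, qtl=qtl, epistatic=epistatic,
        var_target=var_target, gen_corr=gen_corr,
    )
    rescale_on_founders(arch, founders)
    if isinstance(founders, Population):
        founders.traits = arch
        for iid in founders.individuals:
            founders.individuals[iid].tbv = None
    return arch


def rescale_on_founders(arch: TraitArchitecture, founders) -> TraitArchitecture:
    """Affine-normalize effects so founder TBV is exactly (0, var_target).

    Idempotent: applying it to an already-scaled architecture is a no-op.
    Traits with zero realized variance (e.g. no QTL) are centered only.
    """
    if not arch.has_qtl():
        arch.center = np.zeros(arch.n_traits)
        return arch
    mk = arch.all_markers()
    idx = {int(m): i for i, m in enumerate(mk)}
    raw = arch.raw_values(_founder_dosages(founders, mk), idx)
    mean = raw.mean(axis=1)
    var = raw.var(axis=0 if raw.ndim == 1 else 1)
    b = np.where(var > 0, np.sqrt(arch.var_target / np.where(var > 0, var, 1.0)), 1.0)
    for q in arch.qtl:
        q.values *= b[:, None]
    for t in arch.epistatic:
        t.grid *= b[:, None, None]
    arch.center = b * mean
    return arch


def compute_tbv(pop: Population, ids, arch: TraitArchitecture | None = None, cache: bool = True) -> np.ndarray:
    """True breeding values (n_traits x n) of ``ids``; cached on individuals."""
    arch = arch or pop.traits
    if arch is None:
        raise ValueError("population has no trait architecture")
    ids = list(ids)
    if not arch.has_qtl():
        out = np.zeros((arch.n_traits, len(ids)))
    else:
        mk = arch.all_markers()
        idx = {int(m): i for i, m in enumerate(mk)}
        dosages = get_genotypes(pop, ids, markers=mk)
        out = arch.raw_values(dosages, idx) - arch.center[:, None]
    if cache and arch is pop.traits:
        for j, iid in enumerate(ids):
            pop.individuals[iid].tbv = out[:, j].copy()
    return out


def observe_phenotypes(
    pop: Population,
    ids,
    heritability,
    n_obs: int = 1,
    rng: np.random.Generator | None = None,
) -> None:
    """Record averaged phenotype observations for ``ids``.

    ``heritability`` is scalar or per-trait; h2 must lie in (0, 1]. New
    observations are pooled with any existing records by observation count.
    """
    arch = pop.traits
    if arch is None:
        raise ValueError("population has no trait architecture")
    rng = rng if rng is not None else pop.hub["phenotypes"]
    h2 = np.broadcast_to(np.atleast_1d(np.asarray(heritability, dtype=float)), (arch.n_traits,))
    if np.any(h2 <= 0) or np.any(h2 > 1):
        raise ValueError("heritability must lie in (0, 1]; h2 = 0 leaves residual variance undefined")
    sigma_e2 = arch.var_target * (1.0 - h2) / h2
    ids = list(ids)
    tbv = compute_tbv(pop, ids, arch)
    noise = rng.standard_normal((arch.n_traits, len(ids))) * np.sqrt(sigma_e2 / n_obs)[:, None]
    y = tbv + noise
    for j, iid in enumerate(ids):
        ind = pop.individuals[iid]
        if ind.pheno is None:
            ind.pheno = y[:, j].copy()
            ind.pheno_n = np.full(arch.n_traits, n_obs)
        else:
            tot = ind.pheno_n + n_obs
            ind.pheno = (ind.pheno * ind.pheno_n + y[:, j] * n_obs) / tot
            ind.pheno_n = tot
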