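"""Simulation of single meioses.

Crossovers follow the Haldane model: per chromosome the number of crossover
points is Poisson with mean ``scale * length_morgan`` and points are i.i.d.
uniform, with no interference and no obligate chiasma. ``scale`` is the
per-sex map multiplier. De-novo mutations are recurrent allele flips at
existing markers, sampled per marker at a per-meiosis rate (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome
from .population import Gamete, Individual, Population, PopulationError

__all__ = ["MeiosisParams", "sample_crossovers", "compose_gamete", "create_gamete", "mate"]


@dataclass
class MeiosisParams:
    mutation_rate: float = 0.0
    allow_selfing: bool = False

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")


def sample_crossovers(chr_length_morgan: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Sorted crossover positions in (0, L); count ~ Poisson(scale * L)."""
    if chr_length_morgan <= 0:
        return np.empty(0)
    n = rng.poisson(scale * chr_length_morgan)
    return np.sort(rng.uniform(0.0, chr_length_morgan, size=n))


def compose_gamete(
    genome: Genome,
    parent: Individual,
    crossovers: list[np.ndarray],
    start_gametes: list[int],
    denovo: list[np.ndarray],
) -> Gamete:
    """Compose a parent-relative crossover mosaic with the parent's own
    founder-coordinate segments, yielding a gamete resolved to founder
    coordinates. Mutation marks covered by copied pieces are inherited; a
    de-novo flip at an already-flipped marker cancels."""
    ends_out, orig_out, mut_out = [], [], []
    for c in range(genome.n_chr):
        L = genome.chromosomes[c].length_morgan
        pos = genome.chromosomes[c].positions_morgan
        off = int(genome.chr_offsets[c])
        xs = crossovers[c]
        bounds = np.concatenate([[0.0], xs, [L]])
        cur = start_gametes[c]
        ends_c: list[np.ndarray] = []
        orig_c: list[np.ndarray] = []
        muts_c: list[np.ndarray] = [denovo[c]]
        for k in range(len(bounds) - 1):
            a, b = bounds[k], bounds[k + 1]
            if b <= a:
                cur ^= 1
                continue
            pg = parent.gametes[cur]
            p_ends, p_orig = pg.ends[c], pg.origins[c]
            i0 = int(np.searchsorted(p_ends, a, side="right"))
            i1 = int(np.searchsorted(p_ends, b, side="left"))
            ends_c.append(np.concatenate([p_ends[i0:i1], [b]]))
            orig_c.append(p_orig[i0 : i1 + 1])
            pm = pg.mutations[c]
            if pm.size:
                mpos = pos[pm - off]
                muts_c.append(pm[(mpos >= a) & (mpos < b)])
            cur ^= 1
        ends_arr = np.concatenate(ends_c)
        orig_arr = np.concatenate(orig_c)
        # merge adjacent segments copying the same founder row
        if len(orig_arr) > 1:
            keep = np.concatenate([orig_arr[:-1] != orig_arr[1:], [True]])
            ends_arr, orig_arr = ends_arr[keep], orig_arr[keep]
        marks = np.concatenate(muts_c) if muts_c else np.empty(0, dtype=np.int64)
        if marks.size:
            vals, counts = np.unique(marks, return_counts=True)
            marks = vals[counts % 2 == 1]
        ends_out.append(ends_arr)
        orig_out.append(orig_arr.astype(np.int64))
        mut_out.append(marks.astype(np.int64))
    return Gamete(
        ends_out, orig_out, mut_out,
        parent_id=parent.id, crossovers=crossovers, start_gametes=start_gametes, denovo=denovo,
    )


def create_gamete(
    pop: Population,
    parent_id: int,
    params: MeiosisParams,
    rng: np.random.Generator,
    map_scale: float = 1.0,
) -> Gamete:
    """Simulate one meiosis of ``parent_id`` and return the gamete."""
    parent = pop.individuals.get(parent_id)
    if parent is None:
        raise PopulationError(f"unknown parent {parent_id}")
    genome = pop.genome
    crossovers, starts, denovo = [], [], []
    for c in range(genome.n_chr):
        chrom = genome.chromosomes[c]
        crossovers.append(sample_crossovers(chrom.length_morgan, map_scale, rng))
        starts.append(int(rng.integers(0, 2)))
        if params.mutation_rate > 0.0:
            hit = rng.random(chrom.n_snp) < params.mutation_rate
            denovo.append(np.flatnonzero(hit).astype(np.int64) + int(genome.chr_offsets[c]))
        else:
            denovo.append(np.empty(0, dtype=np.int64))
    return compose_gamete(genome, parent, crossovers, starts, denovo)


def mate(
    pop: Population,
    sire_id: int,
    dam_id: int,
    sex: str,
    cohort: str,
    params: MeiosisParams | None = None,
    rng: np.random.Generator | None = None,
    generation: int | None = None,
) -> Individual:
    """Create one offspring of ``sire x dam``.

    The paternal gamete is simulated with the male map scale, the maternal
    with the female scale. The child is appended to ``cohort`` (created if
    needed) and to ``generation`` (default: one past the older parent's)."""
    params = params or MeiosisParams()
    rng = rng if rng is not None else pop.hub["meiosis"]
    sire = pop.individuals.get(sire_id)
    dam = pop.individuals.get(dam_id)
    if sire is None or dam is None:
        raise PopulationError(f"unknown parent in mating ({sire_id}, {dam_id})")
    if not params.allow_selfing:
        if sire_id == dam_id:
            raise PopulationError("selfing requested but allow_selfing is False")
        if sire.sex != "M" or dam.sex != "F":
            raise PopulationError(
                f"sex mismatch: sire {sire_id} is {sire.sex}, dam {dam_id} is {dam.sex}"
            )
    scale_m, scale_f = pop.genome.sex_map_scale
    paternal = create_gamete(pop, sire_id, params, rng, map_scale=scale_m)
    maternal = create_gamete(pop, dam_id, params, rng, map_scale=scale_f)
    gen = generation if generation is not None else max(sire.generation, dam.generation) + 1
    child = Individual(
        id=pop.new_id(), sex=sex, generation=gen, cohort=cohort,
        gametes=[paternal, maternal], sire_id=sire_id, dam_id=dam_id,
    )
    pop.add_individual(child)
    if cohort in pop.cohorts:
        pop.cohorts[cohort].ids.append(child.id)
    else:
        pop.add_cohort(cohort, [child.id], gen, sex)
    return child
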