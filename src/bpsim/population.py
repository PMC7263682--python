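"""Population data model: individuals, generations, cohorts and breakpoint
ancestry.

Full haplotypes are stored for founders only. Every other gamete is a mosaic
of founder haplotype segments — per chromosome an array of segment end
positions (Morgan) and the founder haplotype row each segment copies — plus a
list of de-novo mutations (marker-index allele flips). Haplotypes of
non-founders are never stored; they are derived on demand from the mosaic, so
memory grows with the number of crossovers, not with marker density.

Segments are resolved to founder coordinates eagerly when a gamete is created.
The raw meiosis record (crossover positions, starting parental gamete, de-novo
mutations) is kept alongside, which makes founder re-basing possible and gives
tests an independent derivation path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .genome import FounderHaplotypeStore, Genome, sample_founder_haplotypes
from .rng import RngHub

__all__ = [
    "Segment",
    "Gamete",
    "Individual",
    "Cohort",
    "Population",
    "PopulationError",
    "create_founder_population",
    "resolve_group",
    "derive_haplotype",
    "get_genotypes",
    "rebase_founders",
    "summary_population",
    "format_summary",
    "get_pedigree",
]

MISSING_PARENT = 0  # PLINK-style missing-parent code in pedigree exports


class PopulationError(ValueError):
    pass


class Segment(NamedTuple):
    """Half-open founder-haplotype segment [start, end) on one chromosome."""

    chromosome: int
    start: float
    end: float
    founder_id: int
    founder_gamete: int


class Gamete:
    """One transmitted haploid genome.

    ``ends[c]`` / ``origins[c]`` describe the founder-coordinate mosaic of
    chromosome ``c``: segment ``k`` spans ``[ends[c][k-1], ends[c][k])`` and
    copies founder haplotype row ``origins[c][k]``. ``mutations[c]`` holds
    global marker indices whose allele is flipped relative to the copied
    founder alleles (inherited marks plus this gamete's own de-novo ones).

    The parent-relative meiosis record (``parent_id``, ``crossovers``,
    ``start_gametes``, ``denovo``) is None/empty for founder gametes.
    """

    __slots__ = ("ends", "origins", "mutations", "parent_id", "crossovers", "start_gametes", "denovo")

    def __init__(self, ends, origins, mutations, parent_id=None, crossovers=None, start_gametes=None, denovo=None):
        self.ends = ends
        self.origins = origins
        self.mutations = mutations
        self.parent_id = parent_id
        self.crossovers = crossovers
        self.start_gametes = start_gametes
        self.denovo = denovo

    @classmethod
    def founder(cls, genome: Genome, row: int) -> "Gamete":
        ends = [np.array([c.length_morgan]) for c in genome.chromosomes]
        origins = [np.array([row], dtype=np.int64) for _ in genome.chromosomes]
        muts = [np.empty(0, dtype=np.int64) for _ in genome.chromosomes]
        return cls(ends, origins, muts)

    def n_segments(self) -> int:
        return int(sum(len(e) for e in self.ends))


@dataclass
class Individual:
    id: int
    sex: str  # "M" or "F"
    generation: int  # 1-based
    cohort: str
    gametes: list  # [Gamete, Gamete]
    sire_id: int | None = None
    dam_id: int | None = None
    is_founder: bool = False
    founder_rows: tuple[int, int] | None = None
    tbv: np.ndarray | None = None
    ebv: np.ndarray | None = None
    pheno: np.ndarray | None = None  # mean of stored observations per trait
    pheno_n: np.ndarray | None = None  # observation counts per trait


@dataclass
class Cohort:
    name: str
    ids: list[int]
    generation: int
    sex: str | None = None


class Population:
    """All simulation state: genome, founder store, individuals, groups,
    trait architecture, RNG streams and the action/cost ledger."""

    def __init__(self, genome: Genome, store: FounderHaplotypeStore, hub: RngHub):
        self.genome = genome
        self.store = store
        self.hub = hub
        self.individuals: dict[int, Individual] = {}
        self.generations: list[list[int]] = []
        self.cohorts: dict[str, Cohort] = {}
        self.row_owner: list[tuple[int, int]] = []  # store row -> (founder id, gamete idx)
        self.traits = None  # TraitArchitecture, set by create_traits
        self.ledger: list[dict] = []
        self._next_id = 1
        self._founder_freq_cache: np.ndarray | None = None

    # -- bookkeeping ------------------------------------------------------
    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def add_individual(self, ind: Individual) -> None:
        self.individuals[ind.id] = ind
        while len(self.generations) < ind.generation:
            self.generations.append([])
        self.generations[ind.generation - 1].append(ind.id)

    def add_cohort(self, name: str, ids: list[int], generation: int, sex: str | None) -> None:
        if name in self.cohorts:
            raise PopulationError(f"duplicate cohort name {name!r}")
        self.cohorts[name] = Cohort(name, list(ids), generation, sex)

    @property
    def n_generations(self) -> int:
        return len(self.generations)

    def founder_allele_freqs(self) -> np.ndarray:
        """Empirical allele-1 frequencies of generation 1 (cached)."""
        if self._founder_freq_cache is None:
            geno = get_genotypes(self, self.generations[0])
            self._founder_freq_cache = geno.mean(axis=1) / 2.0
        return self._founder_freq_cache

    def segments_of(self, ind_id: int, gamete_index: int) -> list[Segment]:
        g = self.individuals[ind_id].gametes[gamete_index]
        out = []
        for c in range(self.genome.n_chr):
            start = 0.0
            for end, row in zip(g.ends[c], g.origins[c]):
                fid, fg = self.row_owner[int(row)]
                out.append(Segment(c, start, float(end), fid, fg))
                start = float(end)
        return out


def create_founder_population(
    genome: Genome,
    n_indi: int,
    cohort_name: str = "Founder",
    sex_ratio: float = 0.5,
    seed: int = 0,
    freq_spec=None,
    store: FounderHaplotypeStore | None = None,
    trait_spec: dict | None = None,
) -> Population:
    """Initialize a base population of ``n_indi`` founders.

    Sexes are deterministic: ``ceil(n * sex_ratio)`` males first, the rest
    female. The cohort is split into ``<name>_M`` and ``<name>_F``. Founder
    haplotypes come from ``store`` if given, otherwise they are sampled with
    ``freq_spec`` (see :func:`bpsim.genome.sample_founder_haplotypes`).

    ``trait_spec``, when given, is forwarded to
    :func:`bpsim.traits.create_traits` (keys: n_additive, n_dominant,
    epistatic_spec, n_traits, gen_corr, var_target).
    """
    if n_indi < 1:
        raise PopulationError("need at least one founder")
    hub = RngHub(seed)
    if store is None:
        store = sample_founder_haplotypes(genome, n_indi, freq_spec, seed=hub["founders"])
    if store.n_haplotypes != 2 * n_indi:
        raise PopulationError("store must hold exactly 2 haplotypes per founder")
    pop = Population(genome, store, hub)

    n_male = int(np.ceil(n_indi * sex_ratio - 1e-9))
    males, females = [], []
    for i in range(n_indi):
        sex = "M" if i < n_male else "F"
        iid = pop.new_id()
        rows = (2 * i, 2 * i + 1)
        ind = Individual(
            id=iid, sex=sex, generation=1, cohort=f"{cohort_name}_{sex}",
            gametes=[Gamete.founder(genome, rows[0]), Gamete.founder(genome, rows[1])],
            is_founder=True, founder_rows=rows,
        )
        pop.add_individual(ind)
        pop.row_owner.extend([(iid, 0), (iid, 1)])
        (males if sex == "M" else females).append(iid)
    pop.add_cohort(f"{cohort_name}_M", males, 1, "M")
    pop.add_cohort(f"{cohort_name}_F", females, 1, "F")

    if trait_spec is not None:
        from .traits import create_traits

        create_traits(genome, pop, seed=hub["traits"], **trait_spec)
    return pop


def resolve_group(
    pop: Population,
    gen: Sequence[int] | None = None,
    cohorts: Sequence[str] | None = None,
    database: Sequence[tuple] | None = None,
) -> list[int]:
    """Resolve gen/cohort/database selectors to an ordered, deduplicated id list.

    ``database`` entries are ``(generation, sex)`` or
    ``(generation, sex, (first, last))`` with a 1-based inclusive index range
    into the sex-restricted generation list. With no selector at all the last
    generation is used.
    """
    ids: set[int] = set()
    if gen is None and cohorts is None and database is None:
        gen = [pop.n_generations]
    if gen is not None:
        for g in gen:
            if not 1 <= g <= pop.n_generations:
                raise PopulationError(f"unknown generation {g}")
            ids.update(pop.generations[g - 1])
    if cohorts is not None:
        for name in cohorts:
            if name not in pop.cohorts:
                raise PopulationError(f"unknown cohort {name!r}")
            ids.update(pop.cohorts[name].ids)
    if database is not None:
        for entry in database:
            g, sex = entry[0], entry[1]
            if not 1 <= g <= pop.n_generations:
                raise PopulationError(f"unknown generation {g} in database selector")
            members = [i for i in pop.generations[g - 1] if sex in (None, pop.individuals[i].sex)]
            if len(entry) > 2 and entry[2] is not None:
                first, last = entry[2]
                members = members[first - 1 : last]
            ids.update(members)
    if not ids:
        raise PopulationError(
            f"empty group for selectors gen={gen} cohorts={cohorts} database={database}"
        )
    return sorted(ids)


def derive_haplotype(
    pop: Population, ind_id: int, gamete_index: int, markers: np.ndarray | None = None
) -> np.ndarray:
    """Derive the allele vector of one gamete at all markers (or a subset of
    global marker indices), walking its founder-segment mosaic."""
    ind = pop.individuals.get(ind_id)
    if ind is None:
        raise PopulationError(f"unknown individual {ind_id}")
    g: Gamete = ind.gametes[gamete_index]
    genome = pop.genome
    hap_store = pop.store.unpacked
    if markers is None:
        out = np.empty(genome.total_snps, dtype=np.uint8)
        for c in range(genome.n_chr):
            sl = genome.chr_slice(c)
            out[sl] = _alleles_on_chr(g, c, genome.chromosomes[c].positions_morgan,
                                      np.arange(sl.start, sl.stop), hap_store, pop)
        return out
    markers = np.asarray(markers, dtype=np.int64)
    out = np.empty(markers.size, dtype=np.uint8)
    chr_of = np.searchsorted(genome.chr_offsets, markers, side="right") - 1
    for c in np.unique(chr_of):
        mask = chr_of == c
        mk = markers[mask]
        local = genome.chromosomes[c].positions_morgan[mk - genome.chr_offsets[c]]
        out[mask] = _alleles_on_chr(g, int(c), local, mk, hap_store, pop)
    return out


def _alleles_on_chr(g: Gamete, c: int, positions: np.ndarray, global_idx: np.ndarray,
                    hap_store: np.ndarray, pop: Population) -> np.ndarray:
    ends, origins = g.ends[c], g.origins[c]
    if np.any(origins >= hap_store.shape[0]):
        raise PopulationError("corrupt gamete: segment references a missing founder row")
    seg = np.searchsorted(ends, positions, side="right")
    alleles = hap_store[origins[seg], global_idx]
    muts = g.mutations[c]
    if muts.size:
        flip = np.isin(global_idx, muts)
        alleles = alleles ^ flip.astype(np.uint8)
    return alleles


def get_genotypes(pop: Population, ids: Iterable[int], markers: np.ndarray | None = None) -> np.ndarray:
    """Dosage matrix (markers x individuals) with entries in {0, 1, 2}."""
    ids = list(ids)
    m = pop.genome.total_snps if markers is None else len(markers)
    out = np.empty((m, len(ids)), dtype=np.int8)
    unpacked = pop.store.unpacked
    for j, iid in enumerate(ids):
        ind = pop.individuals.get(iid)
        if ind is None:
            raise PopulationError(f"unknown individual {iid}")
        if ind.is_founder and markers is None:
            r0, r1 = ind.founder_rows
            out[:, j] = unpacked[r0] + unpacked[r1]
        else:
            out[:, j] = derive_haplotype(pop, iid, 0, markers) + derive_haplotype(pop, iid, 1, markers)
    return out


def rebase_founders(pop: Population, generation: int) -> Population:
    """Declare all individuals of ``generation`` new founders.

    Their haplotypes are materialized into the founder store and their
    mosaics collapse to single self-referencing segments; descendants'
    mosaics are recomposed from the stored meiosis records so every retained
    genotype is bit-identical before and after. Memory for earlier ancestry
    can then be reclaimed.
    """
    from .meiosis import compose_gamete  # local import to avoid a cycle

    if not 1 <= generation <= pop.n_generations:
        raise PopulationError(f"unknown generation {generation}")
    gen_ids = pop.generations[generation - 1]
    for iid in gen_ids:
        ind = pop.individuals[iid]
        if ind.is_founder:
            continue
        haps = np.vstack([derive_haplotype(pop, iid, k) for k in (0, 1)])
        first = pop.store.append(haps)
        pop.row_owner.extend([(iid, 0), (iid, 1)])
        ind.founder_rows = (first, first + 1)
        ind.is_founder = True
        ind.sire_id = None
        ind.dam_id = None
        ind.gametes = [Gamete.founder(pop.genome, first), Gamete.founder(pop.genome, first + 1)]
    # recompose all later generations in order so parents are always current
    for g in range(generation, pop.n_generations):
        for iid in pop.generations[g]:
            ind = pop.individuals[iid]
            if ind.is_founder:
                continue
            for k in (0, 1):
                gam = ind.gametes[k]
                parent = pop.individuals[gam.parent_id]
                ind.gametes[k] = compose_gamete(
                    pop.genome, parent, gam.crossovers, gam.start_gametes, gam.denovo
                )
    return pop


def summary_population(pop: Population) -> dict:
    """Deterministic headline counts of the population."""
    sexes = [ind.sex for ind in pop.individuals.values()]
    trait_names = [] if pop.traits is None else list(pop.traits.trait_names)
    return {
        "n_individuals": len(pop.individuals),
        "n_male": sexes.count("M"),
        "n_female": sexes.count("F"),
        "n_generations": pop.n_generations,
        "n_cohorts": len(pop.cohorts),
        "n_chromosomes": pop.genome.n_chr,
        "n_snp": pop.genome.total_snps,
        "total_length_morgan": pop.genome.total_length,
        "n_traits": len(trait_names),
        "trait_names": trait_names,
        "physical_size_bp": pop.genome.physical_size_bp(),
    }


def format_summary(pop: Population) -> str:
    s = summary_population(pop)
    lines = [
        "Population size:",
        f"Total: {s['n_individuals']} individuals",
        f"Of which {s['n_male']} are male and {s['n_female']} are female.",
        f"There are {s['n_generations']} generations and {s['n_cohorts']} unique cohorts.",
        "Genome info:",
        f"There are {s['n_chromosomes']} unique chromosomes.",
        f"In total there are {s['n_snp']} SNPs.",
        f"The genome has a total length of {s['total_length_morgan']:g} Morgan.",
    ]
    if s["physical_size_bp"] is not None:
        lines.append(f"The genome has a physical size of about {s['physical_size_bp']} bp.")
    lines.append("Trait info:")
    if s["n_traits"] == 1:
        lines.append("There is 1 modeled trait.")
    else:
        lines.append(f"There are {s['n_traits']} modeled traits.")
    if s["trait_names"]:
        lines.append("Trait names: " + ", ".join(s["trait_names"]))
    return "\n".join(lines)


def get_pedigree(pop: Population, ids: Iterable[int] | None = None) -> list[tuple[int, int, int]]:
    """(id, sire, dam) triples; founders carry the missing-parent code 0."""
    if ids is None:
        ids = sorted(pop.individuals)
    out = []
    for iid in ids:
        ind = pop.individuals[iid]
        out.append((iid, ind.sire_id or MISSING_PARENT, ind.dam_id or MISSING_PARENT))
    return out
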