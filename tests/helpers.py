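"""Independent oracles and pedigree builders shared by the test suite."""

from __future__ import annotations

import numpy as np

import bpsim
from bpsim.meiosis import MeiosisParams, mate


def eager_haplotypes(pop):
    """Eager-storage twin: full haplotypes for every individual, recomputed
    recursively from the stored meiosis records (crossover positions, start
    gamete, de-novo marks) and the parents' full haplotypes.

    This path never touches the founder-coordinate segment mosaics the
    package derives alleles from, so agreement checks the breakpoint storage
    end to end.
    """
    genome = pop.genome
    cache: dict[tuple[int, int], np.ndarray] = {}

    def hap(iid: int, k: int) -> np.ndarray:
        key = (iid, k)
        if key in cache:
            return cache[key]
        ind = pop.individuals[iid]
        g = ind.gametes[k]
        if g.parent_id is None:
            h = pop.store.unpacked[ind.founder_rows[k]].copy()
        else:
            h = np.empty(genome.total_snps, dtype=np.uint8)
            p0 = hap(g.parent_id, 0)
            p1 = hap(g.parent_id, 1)
            for c, chrom in enumerate(genome.chromosomes):
                sl = genome.chr_slice(c)
                bounds = np.concatenate([[0.0], g.crossovers[c], [chrom.length_morgan]])
                piece = np.searchsorted(bounds, chrom.positions_morgan, side="right") - 1
                src = (piece % 2) ^ g.start_gametes[c]
                h[sl] = np.where(src == 0, p0[sl], p1[sl])
                if g.denovo[c].size:
                    h[g.denovo[c]] ^= 1
        cache[key] = h
        return h

    return {iid: (hap(iid, 0), hap(iid, 1)) for iid in pop.individuals}


def eager_genotypes(pop, ids) -> np.ndarray:
    haps = eager_haplotypes(pop)
    return np.stack([haps[i][0] + haps[i][1] for i in ids], axis=1)


def gene_drop_A(triples, n_reps: int = 100_000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo additive relationship matrix by gene dropping.

    Founders receive unique allele labels; alleles drop through the pedigree
    with fair-coin transmission, vectorized over replicates. Returns the
    estimated A = 2 * coancestry with inbreeding on the diagonal.
    """
    rng = np.random.default_rng(seed)
    parents = {i: (s, d) for i, s, d in triples}
    order = [i for i, _, _ in triples]
    alleles: dict[int, np.ndarray] = {}
    label = 0
    for i in order:
        s, d = parents[i]
        cols = []
        for p in (s, d):
            if p:
                pa = alleles[p]
                pick = rng.integers(0, 2, size=n_reps)
                cols.append(pa[np.arange(n_reps), pick])
            else:
                cols.append(np.full(n_reps, label))
                label += 1
        alleles[i] = np.stack(cols, axis=1)
    n = len(order)
    A = np.empty((n, n))
    for a in range(n):
        for b in range(a, n):
            xa, xb = alleles[order[a]], alleles[order[b]]
            share = sum(
                np.mean(xa[:, u] == xb[:, v]) for u in (0, 1) for v in (0, 1)
            ) / 4.0
            if a == b:
                # A_ii = 1 + F_i, F_i = P(the two alleles of i are IBD)
                A[a, a] = 1.0 + np.mean(xa[:, 0] == xa[:, 1])
            else:
                A[a, b] = A[b, a] = 2.0 * share
    return A


def random_pedigree(pop, n_generations: int, per_gen: int, seed: int = 0,
                    mutation_rate: float = 0.0):
    """Extend a founder population with random matings for a few generations."""
    rng = np.random.default_rng(seed)
    params = MeiosisParams(mutation_rate=mutation_rate)
    for g in range(2, n_generations + 1):
        prev = pop.generations[g - 2]
        males = [i for i in prev if pop.individuals[i].sex == "M"]
        females = [i for i in prev if pop.individuals[i].sex == "F"]
        for k in range(per_gen):
            s = males[rng.integers(len(males))]
            d = females[rng.integers(len(females))]
            sex = "M" if k % 2 == 0 else "F"
            mate(pop, s, d, sex, f"Gen{g}_{sex}", params, pop.hub["meiosis"], generation=g)
    return pop


def small_population(n_indi=20, n_snp=200, n_chr=2, chr_len=1.0, seed=1, freq=0.5):
    genome = bpsim.build_genome(n_chr, chr_len, n_snp)
    return bpsim.create_founder_population(genome, n_indi, seed=seed, freq_spec=freq)
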