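"""Post-hoc population analysis: empirical kinship, breeding-value
development, allele-frequency trajectories and table exports.

Kinship here is identity-by-descent of founder alleles, computed exactly from
the stored segment mosaics: two gametes share descent on the (length-weighted)
part of the genome where they copy the same founder haplotype row. For a pair
(i, j) the coancestry is the probability that one allele sampled at a uniform
genome position from each individual is IBD. The *reported* kinship is
coancestry / 2 by convention — a non-inbred individual then has self-kinship
0.25 and a parent-offspring or full-sib pair an expected 0.125 — with the
plain coancestry exposed alongside. A locus-sampling estimator is available
as a fallback for populations whose segments were discarded by re-basing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import Population, PopulationError, derive_haplotype, get_genotypes, get_pedigree, resolve_group
from .traits import compute_tbv

__all__ = [
    "KinshipEstimate",
    "kinship_emp",
    "pair_coancestry_matrix",
    "group_mean_coancestry",
    "bv_development",
    "analyze_population_freq",
    "export_tables",
    "read_pedigree_table",
]


@dataclass
class KinshipEstimate:
    ids: list[int]
    pairs: list[tuple[int, int]] | None
    kinship: np.ndarray | None  # per requested pair, = coancestry / 2
    coancestry: np.ndarray | None
    group_mean: float | None  # mean kinship over unordered distinct pairs
    group_mean_coancestry: float | None
    n_loci: int | None  # None when computed exactly from segments


def _origin_atoms(pop: Population, ids, c: int):
    """Partition chromosome ``c`` into atomic intervals on which every gamete
    of ``ids`` copies a constant founder row; returns (origins, weights)."""
    gametes = [pop.individuals[i].gametes[k] for i in ids for k in (0, 1)]
    ends = np.unique(np.concatenate([g.ends[c] for g in gametes]))
    starts = np.concatenate([[0.0], ends[:-1]])
    w = ends - starts
    O = np.empty((len(gametes), ends.size), dtype=np.int64)
    for r, g in enumerate(gametes):
        O[r] = g.origins[c][np.searchsorted(g.ends[c], starts, side="right")]
    return O, w


def _origins_at_loci(pop: Population, ids, positions_global: np.ndarray) -> np.ndarray:
    """Founder row of every gamete at sampled genome positions (Morgan on the
    concatenated axis)."""
    genome = pop.genome
    bounds = np.cumsum([0.0] + [c.length_morgan for c in genome.chromosomes])
    chr_idx = np.clip(np.searchsorted(bounds, positions_global, side="right") - 1, 0, genome.n_chr - 1)
    gametes = [pop.individuals[i].gametes[k] for i in ids for k in (0, 1)]
    O = np.empty((len(gametes), positions_global.size), dtype=np.int64)
    for c in range(genome.n_chr):
        mask = chr_idx == c
        if not mask.any():
            continue
        local = positions_global[mask] - bounds[c]
        for r, g in enumerate(gametes):
            O[r, mask] = g.origins[c][np.searchsorted(g.ends[c], local, side="right")]
    return O


def pair_coancestry_matrix(
    pop: Population, ids, n_loci_sample: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Coancestry matrix over ``ids`` (P(IBD) of randomly sampled alleles)."""
    ids = list(ids)
    n = len(ids)
    E = np.zeros((2 * n, 2 * n))
    if n_loci_sample is None:
        total = pop.genome.total_length
        for c in range(pop.genome.n_chr):
            O, w = _origin_atoms(pop, ids, c)
            for a in range(w.size):
                u = O[:, a]
                E += w[a] * (u[:, None] == u[None, :])
        E /= total
    else:
        rng = rng if rng is not None else pop.hub["misc"]
        loci = rng.uniform(0.0, pop.genome.total_length, size=n_loci_sample)
        O = _origins_at_loci(pop, ids, loci)
        for a in range(n_loci_sample):
            u = O[:, a]
            E += (u[:, None] == u[None, :])
        E /= n_loci_sample
    return E.reshape(n, 2, n, 2).sum(axis=(1, 3)) / 4.0


def group_mean_coancestry(pop: Population, ids) -> float:
    """Exact mean coancestry over unordered distinct pairs of ``ids``.

    Equivalent to averaging :func:`pair_coancestry_matrix` off-diagonals but
    computed by per-atom origin counting, which stays fast for large groups.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise PopulationError("group mean kinship needs at least 2 individuals")
    nrow = pop.store.n_haplotypes
    acc = 0.0
    for c in range(pop.genome.n_chr):
        O, w = _origin_atoms(pop, ids, c)
        for a in range(w.size):
            u = O[:, a]
            cnt = np.bincount(u, minlength=nrow)
            s_all = float(np.sum(cnt * cnt))
            own = u.reshape(n, 2)
            s_diag = 2.0 * n + 2.0 * float(np.sum(own[:, 0] == own[:, 1]))
            acc += w[a] * (s_all - s_diag)
    return acc / (pop.genome.total_length * 4.0 * n * (n - 1))


def kinship_emp(
    pop: Population,
    group=None,
    pairs: list[tuple[int, int]] | None = None,
    n_loci_sample: int | None = None,
    rng: np.random.Generator | None = None,
) -> KinshipEstimate:
    """Empirical kinship from founder-segment overlap.

    Either a ``group`` (selector dict or id list; the mean over all unordered
    pairs is reported) or explicit ``pairs``. Exact segment-overlap
    computation by default; ``n_loci_sample`` switches to locus sampling.
    """
    if pairs is not None:
        ids = sorted({i for p in pairs for i in p})
        F = pair_coancestry_matrix(pop, ids, n_loci_sample, rng)
        pos = {iid: k for k, iid in enumerate(ids)}
        co = np.array([F[pos[a], pos[b]] for a, b in pairs])
        return KinshipEstimate(ids, list(pairs), co / 2.0, co, None, None, n_loci_sample)
    if group is None:
        ids = resolve_group(pop)
    elif isinstance(group, dict):
        ids = _as_group(pop, group)
    else:
        ids = list(group)
    if len(ids) < 2:
        raise PopulationError("kinship of a group needs at least 2 individuals")
    if n_loci_sample is None:
        co = group_mean_coancestry(pop, ids)
    else:
        F = pair_coancestry_matrix(pop, ids, n_loci_sample, rng)
        off = ~np.eye(len(ids), dtype=bool)
        co = float(F[off].mean())
    return KinshipEstimate(ids, None, None, None, co / 2.0, co, n_loci_sample)


def _as_group(pop: Population, sel: dict) -> list[int]:
    return resolve_group(pop, gen=sel.get("gen"), cohorts=sel.get("cohorts"), database=sel.get("database"))


def bv_development(pop: Population, groups: dict) -> pd.DataFrame:
    """Per-group mean and variance of TBV, EBV and phenotype.

    ``groups`` maps a label to an id list or selector dict. TBV is in founder
    genomic standard deviations (the trait scaling unit).
    """
    rows = []
    for label, sel in groups.items():
        ids = _as_group(pop, sel) if isinstance(sel, dict) else list(sel)
        row = {"group": label, "n": len(ids)}
        if pop.traits is not None:
            tbv = compute_tbv(pop, ids)
            for t, name in enumerate(pop.traits.trait_names):
                row[f"tbv_mean:{name}"] = tbv[t].mean()
                row[f"tbv_var:{name}"] = tbv[t].var()
                ebv = [pop.individuals[i].ebv[t] for i in ids if pop.individuals[i].ebv is not None]
                row[f"ebv_mean:{name}"] = np.mean(ebv) if ebv else np.nan
                ph = [pop.individuals[i].pheno[t] for i in ids if pop.individuals[i].pheno is not None]
                row[f"pheno_mean:{name}"] = np.mean(ph) if ph else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def analyze_population_freq(pop: Population, marker: int, groups: dict) -> pd.DataFrame:
    """Allele-1 frequency of one global marker index per group."""
    if not 0 <= marker < pop.genome.total_snps:
        raise PopulationError(f"marker {marker} out of range")
    rows = []
    for label, sel in groups.items():
        ids = _as_group(pop, sel) if isinstance(sel, dict) else list(sel)
        dos = get_genotypes(pop, ids, markers=np.array([marker]))
        rows.append({"group": label, "n": len(ids), "freq": dos.mean() / 2.0})
    return pd.DataFrame(rows).set_index("group")


def export_tables(pop: Population, what: str, ids, path) -> None:
    """Write a deterministic TSV of genotypes, phenotypes, EBVs or pedigree.

    Columns are id-sorted; genotype rows are markers (indexed by marker id).
    """
    ids = sorted(ids)
    unknown = [i for i in ids if i not in pop.individuals]
    if unknown:
        raise PopulationError(f"unknown individuals: {unknown}")
    if what == "geno":
        geno = get_genotypes(pop, ids)
        pd.DataFrame(geno, index=pop.genome.marker_ids(), columns=ids).to_csv(path, sep="\t")
    elif what in ("pheno", "ebv"):
        names = ["value"] if pop.traits is None else pop.traits.trait_names
        rows = []
        for i in ids:
            ind = pop.individuals[i]
            vec = ind.pheno if what == "pheno" else ind.ebv
            row = {"id": i}
            for t, nm in enumerate(names):
                row[nm] = np.nan if vec is None else vec[t]
                if what == "pheno":
                    row[f"n_obs:{nm}"] = 0 if ind.pheno_n is None else int(ind.pheno_n[t])
            rows.append(row)
        pd.DataFrame(rows).set_index("id").to_csv(path, sep="\t")
    elif what == "pedigree":
        with open(path, "w") as fh:
            fh.write("id sire dam\n")
            for iid, s, d in get_pedigree(pop, ids):
                fh.write(f"{iid} {s} {d}\n")
    else:
        raise ValueError(f"unknown export {what!r}")


def read_pedigree_table(path) -> list[tuple[int, int, int]]:
    """Read the 3-column whitespace pedigree written by :func:`export_tables`."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if header.split()[:1] != ["id"]:
            fh.seek(0)
        for line in fh:
            if line.strip():
                a, b, c = line.split()[:3]
                out.append((int(a), int(b), int(c)))
    return out


def plot_development(histories: dict, path) -> None:
    """Two-panel plot: mean TBV and mean kinship by generation per scenario.

    ``histories`` maps scenario name to a dict with
    ``mean_tbv_by_generation`` and ``mean_kinship_by_generation`` lists.
    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for name, h in histories.items():
        gens = np.arange(1, len(h["mean_tbv_by_generation"]) + 1)
        axes[0].plot(gens, h["mean_tbv_by_generation"], marker="o", label=name)
        axes[1].plot(gens, h["mean_kinship_by_generation"], marker="o", label=name)
    axes[0].set_xlabel("generation"); axes[0].set_ylabel("mean TBV (founder SD)")
    axes[1].set_xlabel("generation"); axes[1].set_ylabel("mean kinship")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
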