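"""Import/export of genetic maps and genotypes: PLINK .map/.ped and VCF 4.2.

Conventions: .map genetic positions are centiMorgan and divided by 100 on
import; the chromosome length of an imported map is the last marker position
plus a 1e-6 Morgan terminal margin. VCF sites without genetic positions (no
``CM`` INFO field) are converted at 1 cM/Mb. All writers emit a deterministic
column order. Only biallelic SNPs are supported; multi-allelic VCF sites are
skipped with a warning and missing genotypes are an error (no imputation).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome import Chromosome, FounderHaplotypeStore, Genome, MapError
from .population import Population, derive_haplotype, get_pedigree
from .rng import as_rng

__all__ = [
    "read_map_file",
    "write_map_file",
    "read_ped_founders",
    "write_ped_file",
    "read_vcf_founders",
    "write_vcf",
]

TERMINAL_MARGIN = 1e-6  # Morgan appended past the last marker of an imported map
CM_PER_MB = 1.0  # default physical-to-genetic conversion for VCF without CM


def write_map_file(genome: Genome, path) -> None:
    """PLINK .map: chromosome, marker id, genetic position (cM), bp."""
    with open(path, "w") as fh:
        for c in genome.chromosomes:
            bp = c.positions_bp if c.positions_bp is not None else np.rint(c.positions_morgan * 1e8).astype(np.int64)
            for mid, pos, b in zip(c.marker_ids, c.positions_morgan, bp):
                fh.write(f"{c.name}\t{mid}\t{pos * 100.0:.10g}\t{int(b)}\n")


def read_map_file(path) -> Genome:
    """Parse a PLINK .map into a Genome (positions cM -> Morgan)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chr", "id", "cm", "bp"], dtype={"chr": str, "id": str})
    if df.empty:
        raise MapError(f"{path}: empty map file")
    if df["cm"].isna().any():
        raise MapError(f"{path}: missing genetic positions (no bp->cM imputation is done)")
    # chromosomes must appear as contiguous row blocks
    chrom_seq = df["chr"].tolist()
    first_seen: dict[str, int] = {}
    for k, ch in enumerate(chrom_seq):
        if ch in first_seen and chrom_seq[k - 1] != ch:
            raise MapError(f"{path}: chromosome {ch} rows are interleaved with other chromosomes")
        first_seen.setdefault(ch, k)
    if df["id"].duplicated().any():
        warnings.warn(f"{path}: duplicate marker ids; deduplicating with numeric suffixes")
        counts: dict[str, int] = {}
        new_ids = []
        for mid in df["id"]:
            if mid in counts:
                counts[mid] += 1
                new_ids.append(f"{mid}_dup{counts[mid]}")
            else:
                counts[mid] = 0
                new_ids.append(mid)
        df["id"] = new_ids
    chroms = []
    for ch in dict.fromkeys(chrom_seq):
        sub = df[df["chr"] == ch]
        pos = sub["cm"].to_numpy(dtype=float) / 100.0
        if np.any(np.diff(pos) <= 0):
            raise MapError(f"{path}: positions on chromosome {ch} are not strictly increasing")
        chroms.append(
            Chromosome(
                name=str(ch),
                length_morgan=float(pos[-1]) + TERMINAL_MARGIN if pos[-1] > 0 else TERMINAL_MARGIN,
                positions_morgan=pos,
                positions_bp=sub["bp"].to_numpy(dtype=np.int64),
                marker_ids=sub["id"].tolist(),
            )
        )
    return Genome(chromosomes=chroms)


def write_ped_file(pop: Population, ids, path) -> None:
    """PLINK .ped with alleles coded 1 (allele 0) / 2 (allele 1), id-sorted."""
    ids = sorted(ids)
    ped = {i: (s, d) for i, s, d in get_pedigree(pop, ids)}
    with open(path, "w") as fh:
        for i in ids:
            ind = pop.individuals[i]
            h0 = derive_haplotype(pop, i, 0) + 1
            h1 = derive_haplotype(pop, i, 1) + 1
            sex = 1 if ind.sex == "M" else 2
            alleles = " ".join(f"{a} {b}" for a, b in zip(h0, h1))
            fh.write(f"FAM {i} {ped[i][0]} {ped[i][1]} {sex} -9 {alleles}\n")


def read_ped_founders(ped_path, map_path) -> tuple[Genome, FounderHaplotypeStore, pd.DataFrame]:
    """Read founder genotypes from .ped + .map.

    The two alleles of each genotype are taken in file order as the two
    haplotypes (a .ped file carries no phase information; column order is
    used deterministically so write/read round-trips).
    """
    genome = read_map_file(map_path)
    m = genome.total_snps
    haps, meta = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise MapError(f"{ped_path}: expected {6 + 2 * m} columns, found {len(parts)}")
            alleles = np.array(parts[6:], dtype=np.int64)
            if np.any((alleles != 1) & (alleles != 2)):
                raise MapError(f"{ped_path}: missing or non-biallelic allele codes (expect 1/2)")
            haps.append(alleles[0::2] - 1)
            haps.append(alleles[1::2] - 1)
            meta.append({"fid": parts[0], "iid": parts[1], "sire": parts[2], "dam": parts[3], "sex": int(parts[4])})
    store = FounderHaplotypeStore.from_haplotypes(np.asarray(haps, dtype=np.uint8))
    store.freqs = store.unpacked.mean(axis=0)
    return genome, store, pd.DataFrame(meta)


def write_vcf(pop: Population, ids, path) -> None:
    """Minimal VCF 4.2 with phased GT and genetic positions in INFO/CM."""
    ids = sorted(ids)
    genome = pop.genome
    haps = [(derive_haplotype(pop, i, 0), derive_haplotype(pop, i, 1)) for i in ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=bpsim\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position in centiMorgan">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in genome.chromosomes:
            fh.write(f"##contig=<ID={c.name}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(f"indi{i}" for i in ids) + "\n")
        for ci, c in enumerate(genome.chromosomes):
            off = int(genome.chr_offsets[ci])
            bp = c.positions_bp if c.positions_bp is not None else np.rint(c.positions_morgan * 1e8).astype(np.int64)
            for k in range(c.n_snp):
                gt = "\t".join(f"{h0[off + k]}|{h1[off + k]}" for h0, h1 in haps)
                fh.write(
                    f"{c.name}\t{int(bp[k])}\t{c.marker_ids[k]}\tA\tB\t.\t.\t"
                    f"CM={c.positions_morgan[k] * 100.0:.10g}\tGT\t{gt}\n"
                )


def read_vcf_founders(path, seed=0) -> tuple[Genome, FounderHaplotypeStore]:
    """Read phased or unphased founder genotypes from a VCF via cyvcf2.

    Unphased heterozygotes get a seeded random phase. Genetic positions come
    from INFO/CM when present, otherwise from bp at 1 cM/Mb.
    """
    from cyvcf2 import VCF

    rng = as_rng(seed)
    vcf = VCF(str(path))
    n = len(vcf.samples)
    per_chr: dict[str, dict] = {}
    order: list[str] = []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            warnings.warn(f"skipping non-biallelic-SNP site {v.CHROM}:{v.POS}")
            continue
        col = np.empty(2 * n, dtype=np.uint8)
        for s, g in enumerate(v.genotypes):
            a, b, phased = int(g[0]), int(g[1]), bool(g[2])
            if a < 0 or b < 0:
                raise MapError(f"{path}: missing genotype at {v.CHROM}:{v.POS} sample {vcf.samples[s]}")
            if not phased and a != b and rng.integers(0, 2):
                a, b = b, a
            col[2 * s], col[2 * s + 1] = a, b
        cm = v.INFO.get("CM")
        pos_m = float(cm) / 100.0 if cm is not None else v.POS * CM_PER_MB * 1e-8
        if v.CHROM not in per_chr:
            per_chr[v.CHROM] = {"pos": [], "bp": [], "ids": [], "cols": []}
            order.append(v.CHROM)
        d = per_chr[v.CHROM]
        d["pos"].append(pos_m)
        d["bp"].append(v.POS)
        d["ids"].append(v.ID or f"{v.CHROM}:{v.POS}")
        d["cols"].append(col)
    if not order:
        raise MapError(f"{path}: no usable biallelic SNPs")
    chroms, cols = [], []
    for ch in order:
        d = per_chr[ch]
        pos = np.asarray(d["pos"])
        if np.any(np.diff(pos) <= 0):
            raise MapError(f"{path}: genetic positions on {ch} not strictly increasing")
        chroms.append(
            Chromosome(
                name=ch,
                length_morgan=float(pos[-1]) + TERMINAL_MARGIN if pos[-1] > 0 else TERMINAL_MARGIN,
                positions_morgan=pos,
                positions_bp=np.asarray(d["bp"], dtype=np.int64),
                marker_ids=d["ids"],
            )
        )
        cols.extend(d["cols"])
    haps = np.asarray(cols, dtype=np.uint8).T  # (2n, total_snps)
    store = FounderHaplotypeStore.from_haplotypes(haps)
    store.freqs = store.unpacked.mean(axis=0)
    return Genome(chromosomes=chroms), store
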