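"""Genetic map definition and bit-packed founder haplotype storage.

Positions are in Morgan throughout, on 0-based half-open per-chromosome
coordinates ``[0, L)``. Marker indices are 0-based internally and 1-based in
reports and serialized files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rng import as_rng

__all__ = [
    "Chromosome",
    "Genome",
    "FounderHaplotypeStore",
    "build_genome",
    "sample_founder_haplotypes",
    "MapError",
]


class MapError(ValueError):
    """Raised for inconsistent genetic maps (unsorted or out-of-range positions)."""


@dataclass
class Chromosome:
    name: str
    length_morgan: float
    positions_morgan: np.ndarray
    positions_bp: np.ndarray | None = None
    marker_ids: list[str] | None = None

    def __post_init__(self):
        self.positions_morgan = np.asarray(self.positions_morgan, dtype=float)
        if self.length_morgan <= 0:
            raise MapError(f"chromosome {self.name}: length must be > 0")
        p = self.positions_morgan
        if p.size and (np.any(np.diff(p) <= 0)):
            raise MapError(f"chromosome {self.name}: positions not strictly increasing")
        if p.size and (p[0] < 0 or p[-1] >= self.length_morgan):
            raise MapError(
                f"chromosome {self.name}: marker positions must lie in [0, {self.length_morgan})"
            )
        if self.marker_ids is None:
            self.marker_ids = [f"{self.name}_snp{i + 1}" for i in range(p.size)]

    @property
    def n_snp(self) -> int:
        return int(self.positions_morgan.size)


@dataclass
class Genome:
    """Chromosome list plus per-sex recombination map scaling.

    ``sex_map_scale`` multiplies the recombination rate for (male, female)
    meioses; 1 Morgan then corresponds to ``scale`` expected crossovers.
    """

    chromosomes: list[Chromosome]
    sex_map_scale: tuple[float, float] = (1.0, 1.0)
    _offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if not self.chromosomes:
            raise MapError("genome needs at least one chromosome")
        counts = [c.n_snp for c in self.chromosomes]
        self._offsets = np.concatenate([[0], np.cumsum(counts)])

    @property
    def n_chr(self) -> int:
        return len(self.chromosomes)

    @property
    def total_snps(self) -> int:
        return int(self._offsets[-1])

    @property
    def total_length(self) -> float:
        return float(sum(c.length_morgan for c in self.chromosomes))

    @property
    def chr_offsets(self) -> np.ndarray:
        """Global marker index at which each chromosome starts (len n_chr+1)."""
        return self._offsets

    def chr_slice(self, c: int) -> slice:
        return slice(int(self._offsets[c]), int(self._offsets[c + 1]))

    def marker_ids(self) -> list[str]:
        out: list[str] = []
        for c in self.chromosomes:
            out.extend(c.marker_ids)
        return out

    def global_positions(self) -> np.ndarray:
        """Marker positions on a single concatenated Morgan axis."""
        out = []
        off = 0.0
        for c in self.chromosomes:
            out.append(c.positions_morgan + off)
            off += c.length_morgan
        return np.concatenate(out) if out else np.empty(0)

    def chr_of_marker(self) -> np.ndarray:
        """Chromosome index of every global marker index."""
        return np.repeat(np.arange(self.n_chr), np.diff(self._offsets))

    def physical_size_bp(self) -> int | None:
        """Total physical span in bp, only when bp positions were imported."""
        if any(c.positions_bp is None for c in self.chromosomes):
            return None
        return int(sum(int(c.positions_bp[-1]) for c in self.chromosomes if c.n_snp))


def build_genome(
    n_chr: int,
    chr_length_morgan: float,
    n_snp: int,
    positions: list[np.ndarray] | None = None,
    sex_map_scale: tuple[float, float] = (1.0, 1.0),
) -> Genome:
    """Create a genome of ``n_chr`` equal-length chromosomes carrying ``n_snp``
    markers in total, split as evenly as possible.

    Without explicit ``positions`` markers are equidistant with a half-step
    offset from the chromosome ends: marker i of n sits at ``(i + 0.5) * L / n``,
    so no marker coincides with a chromosome boundary.
    """
    if n_chr < 1 or n_snp < 1:
        raise MapError("need n_chr >= 1 and n_snp >= 1")
    if chr_length_morgan <= 0:
        raise MapError("chromosome length must be > 0")
    base, extra = divmod(n_snp, n_chr)
    counts = [base + (1 if i < extra else 0) for i in range(n_chr)]
    chroms = []
    for i, cnt in enumerate(counts):
        if positions is not None:
            pos = np.asarray(positions[i], dtype=float)
        else:
            pos = (np.arange(cnt) + 0.5) * chr_length_morgan / cnt
        chroms.append(Chromosome(name=f"chr{i + 1}", length_morgan=chr_length_morgan, positions_morgan=pos))
    return Genome(chromosomes=chroms, sex_map_scale=sex_map_scale)


class FounderHaplotypeStore:
    """Bit-packed biallelic haplotypes, two rows per founder, 1 bit/marker.

    Rows are appended when later generations are re-based as new founders.
    """

    def __init__(self, packed: np.ndarray, n_snp: int, freqs: np.ndarray | None = None):
        packed = np.ascontiguousarray(packed, dtype=np.uint8)
        if packed.ndim != 2 or packed.shape[1] != (n_snp + 7) // 8:
            raise ValueError("packed array shape inconsistent with n_snp")
        self._packed = packed
        self.n_snp = int(n_snp)
        self.freqs = None if freqs is None else np.asarray(freqs, dtype=float)
        self._unpacked_cache: np.ndarray | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_haplotypes(cls, haplotypes: np.ndarray, freqs: np.ndarray | None = None):
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D (n_haplotypes x n_snp)")
        return cls(cls.pack(haplotypes), haplotypes.shape[1], freqs)

    @staticmethod
    def pack(haplotypes: np.ndarray) -> np.ndarray:
        return np.packbits(np.asarray(haplotypes, dtype=np.uint8), axis=-1)

    @staticmethod
    def unpack(packed: np.ndarray, n_snp: int) -> np.ndarray:
        return np.unpackbits(packed, axis=-1, count=n_snp)

    # -- access -----------------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self._packed.shape[0]

    @property
    def packed(self) -> np.ndarray:
        return self._packed

    @property
    def unpacked(self) -> np.ndarray:
        """All haplotypes as a (n_haplotypes, n_snp) uint8 0/1 matrix (cached)."""
        if self._unpacked_cache is None or self._unpacked_cache.shape[0] != self.n_haplotypes:
            self._unpacked_cache = self.unpack(self._packed, self.n_snp)
        return self._unpacked_cache

    def haplotype(self, row: int) -> np.ndarray:
        return self.unpacked[row]

    def append(self, haplotypes: np.ndarray) -> int:
        """Append haplotype rows; returns the row index of the first new row."""
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        first = self.n_haplotypes
        self._packed = np.vstack([self._packed, self.pack(haplotypes)])
        self._unpacked_cache = None
        return first


def sample_founder_haplotypes(
    genome: Genome,
    n_indi: int,
    freq_spec=None,
    seed=None,
) -> FounderHaplotypeStore:
    """Sample ``2 * n_indi`` founder haplotypes marker-independently.

    ``freq_spec`` gives the allele-1 frequency per marker: a scalar, an array
    of length ``total_snps``, a callable ``f(rng, n_snp) -> array``, or None,
    in which case per-marker frequencies are themselves drawn from U(0, 1)
    (the conventional default for internally sampled base populations).
    """
    rng = as_rng(seed)
    m = genome.total_snps
    if freq_spec is None:
        freqs = rng.uniform(0.0, 1.0, size=m)
    elif callable(freq_spec):
        freqs = np.asarray(freq_spec(rng, m), dtype=float)
    elif np.isscalar(freq_spec):
        freqs = np.full(m, float(freq_spec))
    else:
        freqs = np.asarray(freq_spec, dtype=float)
        if freqs.shape != (m,):
            raise ValueError(f"freq vector must have length {m}")
    if np.any(freqs < 0) or np.any(freqs > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    haps = (rng.random((2 * n_indi, m)) < freqs).astype(np.uint8)
    return FounderHaplotypeStore.from_haplotypes(haps, freqs=freqs)
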