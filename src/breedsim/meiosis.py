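"""Meiosis by founder-origin segment lists.

A chromosome copy of any non-founder is stored not as alleles but as an
ordered list of (start position in cM, founder-haplotype id) pairs: the
"drop-down" representation. Meiosis splices the two parental lists at
crossover breakpoints drawn from a Poisson process on the genetic map
(1 Morgan = 1 expected crossover, no interference), so storage per gamete
grows with map length rather than locus count. Allele states are realized
lazily from the founder haplotype pool only when genotypes are needed.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError
from .genome import GenomeMap

__all__ = [
    "SegmentList",
    "Gamete",
    "FounderHaplotypePool",
    "sample_crossover_positions",
    "recombine_chromosome",
    "form_gamete",
    "realize_haplotype",
]


class SegmentList:
    """One chromosome copy as ordered (start cM, founder-haplotype id) pairs.

    Invariants: first start is 0, starts strictly increase, and
    consecutive origins differ. Segments are half-open ``[start, next)``
    in genetic position, so a locus exactly at a breakpoint belongs to
    the downstream (new-origin) segment.
    """

    __slots__ = ("starts", "origins")

    def __init__(self, starts, origins):
        self.starts = np.asarray(starts, dtype=float)
        self.origins = np.asarray(origins, dtype=np.int64)

    @classmethod
    def founder(cls, haplotype_id: int) -> "SegmentList":
        return cls(np.zeros(1), np.array([haplotype_id], dtype=np.int64))

    def validate(self):
        s, o = self.starts, self.origins
        if s.size == 0 or s[0] != 0.0:
            raise ValidationError("segment list must start at position 0")
        if np.any(np.diff(s) <= 0):
            raise ValidationError("segment starts must be strictly increasing")
        if np.any(o[1:] == o[:-1]):
            raise ValidationError("adjacent segments must differ in origin")

    def origin_at(self, positions) -> np.ndarray:
        """Founder-haplotype id covering each genetic position (cM)."""
        idx = np.searchsorted(self.starts, np.asarray(positions, dtype=float),
                              side="right") - 1
        return self.origins[idx]

    def __len__(self):
        return self.starts.size

    def __repr__(self):
        pairs = list(zip(np.round(self.starts, 4).tolist(), self.origins.tolist()))
        return f"SegmentList({pairs})"


class Gamete:
    """A haploid genome copy: one SegmentList per chromosome plus any
    de-novo mutation events (global locus indices whose allele flips at
    realization; founder haplotypes themselves are never altered)."""

    __slots__ = ("chromosomes", "mutations")

    def __init__(self, chromosomes: list[SegmentList], mutations=None):
        self.chromosomes = chromosomes
        self.mutations = mutations  # int array of locus indices, or None

    @classmethod
    def founder(cls, haplotype_id: int, n_chr: int) -> "Gamete":
        return cls([SegmentList.founder(haplotype_id) for _ in range(n_chr)])

    @property
    def n_segments(self) -> int:
        return sum(len(c) for c in self.chromosomes)


class FounderHaplotypePool:
    """Registry of founder haplotypes: id -> full-genome 0/1 allele vector."""

    def __init__(self, n_loci: int):
        self.n_loci = n_loci
        self._haplotypes: list[np.ndarray] = []

    def add(self, alleles: np.ndarray) -> int:
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.shape != (self.n_loci,):
            raise ValidationError("haplotype length must equal the locus count")
        self._haplotypes.append(alleles)
        return len(self._haplotypes) - 1

    def __getitem__(self, hid: int) -> np.ndarray:
        return self._haplotypes[hid]

    def __len__(self):
        return len(self._haplotypes)


# ---------------------------------------------------------------------------
# Crossover sampling and splicing
# ---------------------------------------------------------------------------

def sample_crossover_positions(chrom_length_morgan: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Crossover breakpoints (cM, sorted) for one meiosis on one chromosome.

    The count is Poisson with mean equal to the map length in Morgans and
    positions are i.i.d. uniform along the chromosome — no interference,
    no obligate chiasma.
    """
    if chrom_length_morgan < 0:
        raise ValidationError("chromosome length cannot be negative")
    k = rng.poisson(chrom_length_morgan)
    if k == 0:
        return np.empty(0)
    return np.sort(rng.uniform(0.0, chrom_length_morgan * 100.0, size=k))


def recombine_chromosome(copy0: SegmentList, copy1: SegmentList,
                         crossovers: np.ndarray, start_copy: int) -> SegmentList:
    """Splice two parental segment lists at the given breakpoints.

    Walk the chromosome left to right starting on ``copy0`` or ``copy1``
    per ``start_copy``; at each crossover switch to the other copy,
    carrying over its segments for the next interval. Adjacent segments
    with equal origin are merged.
    """
    lists = (copy0, copy1)
    cur = int(start_copy)
    starts_out: list[float] = []
    origins_out: list[int] = []
    bounds = np.concatenate([crossovers, [np.inf]])
    lo = 0.0
    for hi in bounds:
        src = lists[cur]
        i = np.searchsorted(src.starts, lo, side="right") - 1
        j = np.searchsorted(src.starts, hi, side="left")
        first = True
        for k in range(i, j):
            start = lo if first else float(src.starts[k])
            first = False
            origin = int(src.origins[k])
            if origins_out and origins_out[-1] == origin:
                continue  # merge with previous segment
            starts_out.append(start)
            origins_out.append(origin)
        cur ^= 1
        lo = float(hi)
    return SegmentList(np.array(starts_out), np.array(origins_out, dtype=np.int64))


def form_gamete(parent, genome: GenomeMap, rng: np.random.Generator) -> Gamete:
    """One meiosis: recombine the parent's two genome copies per chromosome.

    The starting parental copy is chosen with probability 1/2 per
    chromosome; crossover breakpoints follow
    :func:`sample_crossover_positions`. With a positive genome mutation
    rate, each locus flips independently on the transmitted gamete and
    the flips are recorded as exception events on the gamete.
    """
    pat, mat = parent.gametes
    chroms = []
    for c in range(genome.n_chr):
        xs = sample_crossover_positions(float(genome.lengths_morgan[c]), rng)
        start_copy = int(rng.integers(2))
        chroms.append(recombine_chromosome(pat.chromosomes[c], mat.chromosomes[c],
                                           xs, start_copy))
    mutations = None
    if genome.mutation_rate > 0:
        hits = np.flatnonzero(rng.random(genome.n_loci) < genome.mutation_rate)
        if hits.size:
            mutations = hits
    return Gamete(chroms, mutations)


def realize_haplotype(gamete: Gamete, pool: FounderHaplotypePool,
                      genome: GenomeMap) -> np.ndarray:
    """Allele vector (0/1, length n_loci) encoded by a gamete.

    Each locus takes the allele of the founder haplotype whose half-open
    segment covers its genetic position; recorded mutation events then
    flip their loci.
    """
    out = np.empty(genome.n_loci, dtype=np.int8)
    for c, seg in enumerate(gamete.chromosomes):
        sl = genome.chrom_slices[c]
        pos = genome.cM[sl]
        # Loci are sorted by position, so each segment covers a contiguous run.
        cut = np.searchsorted(pos, seg.starts[1:], side="left")
        bounds = np.concatenate([[0], cut, [pos.size]])
        for k in range(len(seg)):
            i, j = bounds[k], bounds[k + 1]
            if i < j:
                out[sl.start + i: sl.start + j] = \
                    pool[int(seg.origins[k])][sl.start + i: sl.start + j]
    if gamete.mutations is not None:
        out[gamete.mutations] ^= 1
    return out
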