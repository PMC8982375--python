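"""Shared fixtures and independent oracles for the test suite.

The per-locus gene-dropping oracle here deliberately avoids the segment
representation: it tracks explicit allele vectors through each meiosis,
so agreement with the segment engine is a genuine cross-check.
"""

import numpy as np
import pandas as pd
import pytest

import breedsim as bs


@pytest.fixture
def tiny_genome():
    """The 4-loci-on-2-chromosomes quick-start genome."""
    return bs.build_genome(n_chr=2, n_loci=2)


@pytest.fixture
def line_genome():
    """One 1-Morgan chromosome with 10 irregularly spaced loci."""
    cM = [0.0, 3.0, 10.0, 29.999, 30.0, 42.5, 55.0, 70.0, 88.0, 100.0]
    return bs.GenomeMap(["1"] * 10, cM, lengths_morgan=1.0)


@pytest.fixture
def map_csv(tmp_path):
    """A 4-row map file with chr/cM/bp/maf and two trait-effect columns."""
    path = tmp_path / "map.csv"
    path.write_text(
        "# demo map\n"
        "chr,cM,bp,maf,eff_1,eff_2\n"
        "1,0.0,1,0.5,0.4,0.0\n"
        "1,50.0,500000,0.3,0.0,0.2\n"
        "2,25.0,250000,0.1,-0.6,0.0\n"
        "2,75.0,750000,0.5,0.0,0.0\n")
    return path


def naive_gamete_alleles(parent_haps: np.ndarray, genome: bs.GenomeMap,
                         crossovers, start_copies,
                         mutations=None) -> np.ndarray:
    """Per-locus inheritance oracle for one meiosis.

    ``parent_haps`` is the parent's explicit (2, n_loci) allele matrix.
    For each chromosome the active copy starts at ``start_copies[c]`` and
    flips at every crossover; a locus exactly at a breakpoint takes the
    new copy. Mutation events (global locus indices) flip alleles.
    """
    out = np.empty(genome.n_loci, dtype=np.int8)
    for c, sl in enumerate(genome.chrom_slices):
        pos = genome.cM[sl]
        switches = np.searchsorted(np.asarray(crossovers[c], dtype=float),
                                   pos, side="right")
        copy = (start_copies[c] + switches) % 2
        out[sl] = np.where(copy == 0, parent_haps[0, sl], parent_haps[1, sl])
    if mutations is not None:
        out[np.asarray(mutations, dtype=int)] ^= 1
    return out


def engine_gamete(parent: bs.Individual, genome: bs.GenomeMap,
                  crossovers, start_copies) -> bs.Gamete:
    """Build a gamete through the segment engine from fixed meiosis events."""
    pat, mat = parent.gametes
    chroms = [bs.recombine_chromosome(pat.chromosomes[c], mat.chromosomes[c],
                                      np.asarray(crossovers[c], dtype=float),
                                      start_copies[c])
              for c in range(genome.n_chr)]
    return bs.Gamete(chroms)


def three_generation_pedigree() -> pd.DataFrame:
    """Founders 1-2, full sibs 3-4, their offspring 5-6 (full-sib mating)."""
    return pd.DataFrame({"id": [1, 2, 3, 4, 5, 6],
                         "sire": [0, 0, 1, 1, 3, 3],
                         "dam": [0, 0, 2, 2, 4, 4]})
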