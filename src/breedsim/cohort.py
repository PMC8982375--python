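"""Individuals, cohorts, and founder creation.

A :class:`Simulation` owns the shared state of one simulated population:
the genome, the phenome, the founder-haplotype pool, the id counter, and
a single seedable random generator threaded through every stochastic
operation. Cohorts are ordered, immutable views over individuals and
support the overloaded algebra (``+`` concatenation, 1-based subsetting,
``sample``, ``sort``, and ``*`` for default random mating).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .genome import GenomeMap, Phenome
from .meiosis import FounderHaplotypePool, Gamete, realize_haplotype

__all__ = ["Simulation", "Individual", "Cohort", "sort_cohort", "sample_cohort"]

_MISSING = (-1, 9)


class Individual:
    """One diploid individual: two gametes per genome, parent ids, sex,
    and lazily filled breeding values / phenotypes / EBV.

    Phenotypes are sticky: once drawn they are fixed for the lifetime of
    the individual unless explicitly re-simulated, so repeated selection
    on phenotypes is reproducible.
    """

    __slots__ = ("id", "sire", "dam", "sex", "gametes", "_bv", "phenotypes", "ebv")

    def __init__(self, id: int, gametes: tuple[Gamete, Gamete],
                 sire: "Individual | None" = None,
                 dam: "Individual | None" = None, sex: str | None = None):
        self.id = id
        self.gametes = gametes
        self.sire = sire
        self.dam = dam
        self.sex = sex          # "male" | "female" | None
        self._bv = None         # per-trait true breeding value, cached
        self.phenotypes = None  # per-trait observed value, sticky
        self.ebv = None         # per-trait estimate, set by evaluation

    @property
    def sire_id(self) -> int:
        return self.sire.id if self.sire is not None else 0

    @property
    def dam_id(self) -> int:
        return self.dam.id if self.dam is not None else 0

    def haplotypes(self, sim: "Simulation") -> np.ndarray:
        """Realized (2, n_loci) 0/1 allele matrix for the two gametes."""
        return np.stack([realize_haplotype(g, sim.pool, sim.genome)
                         for g in self.gametes])

    def dosage(self, sim: "Simulation") -> np.ndarray:
        """True allele dosage (0/1/2) per locus, free of genotyping error."""
        return self.haplotypes(sim).sum(axis=0)

    def breeding_values(self, sim: "Simulation") -> np.ndarray:
        if self._bv is None:
            self._bv = sim.phenome.effects.T @ self.dosage(sim).astype(float)
        return self._bv

    def origins_at(self, chrom: int, position_cM: float) -> tuple[int, int]:
        """Founder-haplotype ids carried by the two copies at a map position
        (useful for identity-by-descent bookkeeping)."""
        return tuple(int(g.chromosomes[chrom].origin_at([position_cM])[0])
                     for g in self.gametes)

    def __repr__(self):
        return (f"Individual(id={self.id}, sire={self.sire_id}, "
                f"dam={self.dam_id}, sex={self.sex})")


class Simulation:
    """Shared context of a simulated population.

    Parameters
    ----------
    genome : GenomeMap
    phenome : Phenome, optional
        Required only for breeding values, phenotypes, and evaluation.
    seed : int or numpy Generator, optional
        Seeds the single generator used by every stochastic operation
        run against this simulation; a fixed seed makes whole breeding
        programs bit-reproducible.
    """

    def __init__(self, genome: GenomeMap, phenome: Phenome | None = None,
                 seed=None):
        if phenome is not None and phenome.effects.shape[0] != genome.n_loci:
            raise ValidationError("phenome effects do not match the genome size")
        self.genome = genome
        self.phenome = phenome
        self.rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        self.pool = FounderHaplotypePool(genome.n_loci)
        self._next_id = 1

    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def _new_founder(self, haps: np.ndarray) -> Individual:
        h0 = self.pool.add(haps[0])
        h1 = self.pool.add(haps[1])
        gametes = (Gamete.founder(h0, self.genome.n_chr),
                   Gamete.founder(h1, self.genome.n_chr))
        return Individual(self.new_id(), gametes)

    def _bernoulli_haplotypes(self, shape) -> np.ndarray:
        """Allele 1 (the reference allele) with probability 1 - MAF."""
        return (self.rng.random(shape) < (1.0 - self.genome.maf)).astype(np.int8)

    # -- founder creation ---------------------------------------------------

    def founders(self, source=0) -> "Cohort":
        """Create a founder cohort.

        ``source`` may be a count (alleles drawn Bernoulli(1 - MAF) per
        locus, linkage and Hardy-Weinberg equilibria), a haplotype CSV
        (two 0/1 columns per locus), or a genotype CSV (one 0/1/2 dosage
        column per locus, heterozygote phase randomized). Missing codes
        -1 and 9 are imputed by the Bernoulli rule. ``founders(0)``
        returns an empty cohort usable as a concatenation seed.
        """
        if isinstance(source, (str, Path)):
            return self._founders_from_file(source)
        n = int(source)
        if n < 0:
            raise ValidationError("founder count cannot be negative")
        members = [self._new_founder(self._bernoulli_haplotypes((2, self.genome.n_loci)))
                   for _ in range(n)]
        return Cohort(self, members)

    def _founders_from_file(self, path) -> "Cohort":
        path = Path(path)
        data = pd.read_csv(path, header=None, comment="#").to_numpy()
        n_loci = self.genome.n_loci
        if data.shape[1] == 2 * n_loci:
            return self._founders_from_haplotypes(data)
        if data.shape[1] == n_loci:
            return self._founders_from_genotypes(data)
        raise FormatError(
            f"{path}: {data.shape[1]} columns; expected {n_loci} (genotypes) "
            f"or {2 * n_loci} (haplotypes) for this genome")

    def _founders_from_haplotypes(self, data: np.ndarray) -> "Cohort":
        valid = {0, 1, *_MISSING}
        if not set(np.unique(data)).issubset(valid):
            raise ValidationError("haplotype entries must be 0/1 (or -1/9 missing)")
        members = []
        for row in data:
            # Columns (2j-1, 2j) are the paternal/maternal alleles of locus j.
            haps = row.reshape(-1, 2).T.astype(np.int8)
            missing = np.isin(haps, _MISSING)
            if missing.any():
                haps = np.where(missing, self._bernoulli_haplotypes((2, haps.shape[1])),
                                haps)
            members.append(self._new_founder(haps))
        return Cohort(self, members)

    def _founders_from_genotypes(self, data: np.ndarray) -> "Cohort":
        valid = {0, 1, 2, *_MISSING}
        if not set(np.unique(data)).issubset(valid):
            raise ValidationError("dosages must be 0/1/2 (or -1/9 missing)")
        members = []
        for row in data:
            dose = row.astype(np.int8)
            missing = np.isin(dose, _MISSING)
            haps = np.zeros((2, dose.size), dtype=np.int8)
            haps[:, dose == 2] = 1
            het = dose == 1
            phase = self.rng.integers(2, size=int(het.sum()))
            haps[0, np.flatnonzero(het)] = phase
            haps[1, np.flatnonzero(het)] = 1 - phase
            if missing.any():
                imput = self._bernoulli_haplotypes((2, dose.size))
                haps = np.where(missing, imput, haps)
            members.append(self._new_founder(haps))
        return Cohort(self, members)


class Cohort:
    """An ordered collection of individuals bound to one simulation.

    The algebra never mutates members: ``A + B`` concatenates, ``A[i:j]``
    is the 1-based inclusive subset sharing the same Individual objects,
    ``sample`` draws members, ``A * B`` random-mates the two cohorts.
    Iteration yields single-individual cohorts so loops compose with the
    mating operators.
    """

    def __init__(self, sim: Simulation, members: Iterable[Individual]):
        self.sim = sim
        self.members: list[Individual] = list(members)

    # -- basics -------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.members)

    def __len__(self):
        return len(self.members)

    @property
    def ids(self) -> np.ndarray:
        return np.array([m.id for m in self.members], dtype=np.int64)

    def __iter__(self):
        return (Cohort(self.sim, [m]) for m in self.members)

    def __repr__(self):
        return f"Cohort(n={self.n})"

    # -- algebra ------------------------------------------------------------

    def __add__(self, other: "Cohort") -> "Cohort":
        if not isinstance(other, Cohort):
            return NotImplemented
        if other.n and self.n and other.sim is not self.sim:
            raise ValidationError("cannot concatenate cohorts from different simulations")
        sim = self.sim if self.n or not other.n else other.sim
        return Cohort(sim, self.members + other.members)

    def __getitem__(self, key) -> "Cohort":
        """1-based inclusive subsetting: ``A[1:5]`` is the first five."""
        if isinstance(key, slice):
            if key.step not in (None, 1):
                raise IndexError("stepped cohort slices are not supported")
            lo = 1 if key.start is None else int(key.start)
            hi = self.n if key.stop is None else int(key.stop)
            if lo < 1 or hi > self.n or lo > hi:
                raise IndexError(f"slice [{lo}:{hi}] out of range for n={self.n}")
            return Cohort(self.sim, self.members[lo - 1: hi])
        if isinstance(key, (list, np.ndarray)):
            idx = np.asarray(key, dtype=int)
            if np.any((idx < 1) | (idx > self.n)):
                raise IndexError("cohort index out of range")
            return Cohort(self.sim, [self.members[i - 1] for i in idx])
        i = int(key)
        if not 1 <= i <= self.n:
            raise IndexError(f"index {i} out of range for n={self.n}")
        return Cohort(self.sim, [self.members[i - 1]])

    def __mul__(self, other: "Cohort") -> "Cohort":
        from .mating import mate
        return mate(self, other)

    def sample(self, k: int, replace: bool = False, rng=None) -> "Cohort":
        rng = self.sim.rng if rng is None else rng
        if not replace and k > self.n:
            raise ValidationError(f"cannot sample {k} from {self.n} without replacement")
        idx = rng.choice(self.n, size=k, replace=replace)
        return Cohort(self.sim, [self.members[i] for i in idx])

    # -- quantitative accessors --------------------------------------------

    def get_genotypes(self, error_rate: float | None = None, rng=None) -> np.ndarray:
        """(n, n_loci) dosage matrix.

        With a positive genotyping error rate (the genome's by default),
        each call is independently perturbed to one of the other two
        dosage values. Errors touch reported genotypes only; inheritance
        always uses the true haplotypes.
        """
        M = np.stack([m.dosage(self.sim) for m in self.members]) if self.n \
            else np.empty((0, self.sim.genome.n_loci), dtype=np.int8)
        e = self.sim.genome.genotyping_error_rate if error_rate is None else error_rate
        if e > 0 and M.size:
            rng = self.sim.rng if rng is None else rng
            hit = rng.random(M.shape) < e
            # Replace an erroneous call uniformly with one of the other two values.
            shift = rng.integers(1, 3, size=M.shape)
            M = np.where(hit, (M + shift) % 3, M).astype(np.int8)
        return M

    def get_BVs(self) -> np.ndarray:
        """(n, n_traits) true breeding values."""
        return np.stack([m.breeding_values(self.sim) for m in self.members]) \
            if self.n else np.empty((0, self.sim.phenome.n_traits))

    def get_phenotypes(self, rng=None) -> np.ndarray:
        from .evaluation import simulate_phenotypes
        return simulate_phenotypes(self, rng=rng)

    def get_EBVs(self) -> np.ndarray:
        if any(m.ebv is None for m in self.members):
            raise ValidationError("EBV not computed for this cohort; run an evaluation")
        return np.stack([m.ebv for m in self.members])

    # -- summaries and I/O --------------------------------------------------

    def get_pedigree(self, ancestors: bool = True) -> pd.DataFrame:
        """Pedigree table (id, sire, dam), ancestors first (0 = unknown).

        With ``ancestors=True`` every reachable ancestor is included, so
        the table is always topologically valid: creation ids increase
        from parent to offspring.
        """
        seen: dict[int, Individual] = {}
        stack = list(self.members)
        while stack:
            m = stack.pop()
            if m.id in seen:
                continue
            seen[m.id] = m
            if ancestors:
                stack.extend(p for p in (m.sire, m.dam) if p is not None)
        rows = sorted(seen.values(), key=lambda m: m.id)
        return pd.DataFrame({"id": [m.id for m in rows],
                             "sire": [m.sire_id for m in rows],
                             "dam": [m.dam_id for m in rows]})

    def get_summary(self, outdir=None, prefix: str = "cohort") -> dict:
        """Pedigree, true BVs, phenotypes, ids and sexes; optionally saved
        as CSV files ``<prefix>_{pedigree,bv,phenotypes,info}.csv``."""
        ped = self.get_pedigree()
        info = pd.DataFrame({"id": self.ids,
                             "sire": [m.sire_id for m in self.members],
                             "dam": [m.dam_id for m in self.members],
                             "sex": [m.sex or "unspecified" for m in self.members]})
        out = {"pedigree": ped, "info": info}
        if self.sim.phenome is not None:
            t = self.sim.phenome.n_traits
            out["bv"] = pd.DataFrame(self.get_BVs(),
                                     columns=[f"bv_{i+1}" for i in range(t)],
                                     index=pd.Index(self.ids, name="id"))
            phen = [m.phenotypes if m.phenotypes is not None
                    else np.full(t, np.nan) for m in self.members]
            out["phenotypes"] = pd.DataFrame(
                np.array(phen).reshape(self.n, t) if self.n else np.empty((0, t)),
                columns=[f"y_{i+1}" for i in range(t)],
                index=pd.Index(self.ids, name="id"))
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            ped.to_csv(outdir / f"{prefix}_pedigree.csv", index=False)
            info.to_csv(outdir / f"{prefix}_info.csv", index=False)
            if "bv" in out:
                out["bv"].to_csv(outdir / f"{prefix}_bv.csv")
                out["phenotypes"].to_csv(outdir / f"{prefix}_phenotypes.csv")
        return out

    def sort(self, by: str = "BV", weights=None) -> "Cohort":
        return sort_cohort(self, by=by, weights=weights)


def _index_scores(cohort: Cohort, values: np.ndarray, weights) -> np.ndarray:
    t = values.shape[1]
    w = np.ones(t) if weights is None else np.asarray(weights, dtype=float)
    if w.size != t:
        raise ValidationError("weights length must equal the number of traits")
    return values @ w


def sort_cohort(cohort: Cohort, by: str = "BV", weights=None) -> Cohort:
    """Return a new cohort sorted by the requested key.

    ``by`` is one of ``"BV"``, ``"EBV"``, ``"phenotypes"`` (descending
    weighted index, default weights all 1; ties broken by id), a single
    trait phenotype key like ``"y1"``, or ``"pedigree"`` (oldest first,
    i.e. ascending creation id).
    """
    if by == "pedigree":
        order = np.argsort(cohort.ids, kind="stable")
        return Cohort(cohort.sim, [cohort.members[i] for i in order])
    if by == "BV":
        scores = _index_scores(cohort, cohort.get_BVs(), weights)
    elif by == "EBV":
        scores = _index_scores(cohort, cohort.get_EBVs(), weights)
    elif by == "phenotypes":
        scores = _index_scores(cohort, cohort.get_phenotypes(), weights)
    elif by.startswith("y") and by[1:].isdigit():
        trait = int(by[1:]) - 1
        y = cohort.get_phenotypes()
        if not 0 <= trait < y.shape[1]:
            raise ValidationError(f"unknown trait key {by!r}")
        scores = y[:, trait]
    else:
        raise ValidationError(f"unknown sort key {by!r}")
    # Descending score, ascending id on ties (stable two-key sort).
    order = np.lexsort((cohort.ids, -scores))
    return Cohort(cohort.sim, [cohort.members[i] for i in order])


def sample_cohort(cohort: Cohort, k: int, replace: bool = False, rng=None) -> Cohort:
    """Module-level alias of :meth:`Cohort.sample`."""
    return cohort.sample(k, replace=replace, rng=rng)
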