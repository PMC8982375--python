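"""Mating schemes: the general `mate` operator, pedigree-driven mating,
and doubled-haploid production.

Every scheme is a parameterization of one loop: choose ``nA`` common
parents from cohort A, give each ``nB_per_A`` mates from cohort B, and
produce ``n_per_mate`` offspring per pair, so the offspring count is
always exactly ``nA * nB_per_A * n_per_mate``. Named schemes only preset
the arguments (random, diallel cross, selfing); technologies like ovum
pick-up are expressed by role-swapping the cohorts rather than by
special-case code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, Individual, Simulation
from .exceptions import FormatError, ValidationError
from .meiosis import form_gamete

__all__ = ["MatingArgs", "mate", "mate_from_pedigree", "get_DH"]

_SCHEMES = ("random", "diallel cross", "selfing", "pedigree")


@dataclass
class MatingArgs:
    """Validated arguments of one `mate` call.

    ``ratio_malefemale`` is the male:female ratio among offspring
    (``False``/0 keeps sexes unassigned and returns a single cohort).
    """

    nA: int
    nB_per_A: int = 1
    replace_A: bool = False
    replace_B: bool = False
    n_per_mate: int = 1
    ratio_malefemale: float | bool = False
    scheme: str | None = None

    def validate(self, n_A: int, n_B: int):
        if self.scheme is not None and self.scheme not in _SCHEMES:
            raise ValidationError(f"unknown mating scheme {self.scheme!r}")
        if self.n_per_mate < 1:
            raise ValidationError("n_per_mate must be at least 1")
        if self.nA < 1 or self.nB_per_A < 1:
            raise ValidationError("nA and nB_per_A must be at least 1")
        if not self.replace_A and self.nA > n_A:
            raise ValidationError(f"nA={self.nA} exceeds |A|={n_A} without replacement")
        if self.scheme != "selfing" and not self.replace_B and self.nB_per_A > n_B:
            raise ValidationError(
                f"nB_per_A={self.nB_per_A} exceeds |B|={n_B} without replacement")
        r = self.ratio_malefemale
        if r is not False and r is not None and float(r) < 0:
            raise ValidationError("ratio_malefemale must be nonnegative or False")


def _sample_parents(members, k, replace, rng):
    if replace:
        idx = rng.integers(0, len(members), size=k)
    else:
        if k > len(members):
            raise ValidationError(
                f"cannot draw {k} parents from {len(members)} without replacement")
        idx = rng.permutation(len(members))[:k]
    return [members[i] for i in idx]


def _make_offspring(sim: Simulation, sire: Individual, dam: Individual,
                    rng) -> Individual:
    gametes = (form_gamete(sire, sim.genome, rng),
               form_gamete(dam, sim.genome, rng))
    return Individual(sim.new_id(), gametes, sire=sire, dam=dam)


def _assign_sexes(offspring: list[Individual], ratio: float):
    """Deterministic interleaved sexing at the exact rounded male count."""
    total = len(offspring)
    n_males = int(np.floor(total * ratio / (1.0 + ratio) + 0.5))
    males, females = [], []
    acc = 0
    for i, ind in enumerate(offspring):
        nxt = (i + 1) * n_males // total if total else 0
        if nxt > acc:
            ind.sex = "male"
            males.append(ind)
        else:
            ind.sex = "female"
            females.append(ind)
        acc = nxt
    return males, females


def mate(A: Cohort, B: Cohort | None = None, *, nA=None, nB_per_A=None,
         replace_A=False, replace_B=False, n_per_mate=1,
         ratio_malefemale=False, scheme=None, rng=None, **_ignored):
    """Mate two cohorts (or one cohort with itself) and return offspring.

    Defaults reproduce random mating: every member of A is a common
    parent, each mated once to a mate drawn from B without replacement
    (within A, excluding self-pairing, when B is omitted). Named schemes
    preset the arguments:

    - ``"diallel cross"``: every A x B pair (``nA=|A|, nB_per_A=|B|``);
    - ``"selfing"``: each of ``nA`` parents from A is selfed
      ``n_per_mate`` times (no second cohort allowed).

    With a truthy ``ratio_malefemale`` r the offspring are sexed
    deterministically, interleaved in mating order with exactly
    ``round(total * r / (1 + r))`` males, and a (males, females) pair of
    cohorts is returned; otherwise a single unsexed cohort.

    Extra keyword arguments (e.g. the selection keys of a combined
    `breed` argument dict) are ignored, so one dict can drive both
    mating and selection.
    """
    sim = A.sim
    rng = sim.rng if rng is None else rng
    if A.n == 0:
        raise ValidationError("cannot mate an empty cohort")
    selfing = scheme == "selfing"
    if selfing and B is not None:
        raise ValidationError("selfing takes a single cohort")

    within = B is None and not selfing
    pool_B = A if within or selfing else B
    if pool_B.n and pool_B.sim is not sim:
        raise ValidationError("cohorts belong to different simulations")

    if scheme == "diallel cross":
        nA = A.n if nA is None else nA
        nB_per_A = pool_B.n if nB_per_A is None else nB_per_A
    else:
        nA = A.n if nA is None else nA
        nB_per_A = 1 if nB_per_A is None else nB_per_A
    args = MatingArgs(nA, nB_per_A, replace_A, replace_B, n_per_mate,
                      ratio_malefemale, scheme)
    args.validate(A.n, pool_B.n)

    offspring: list[Individual] = []
    parents_A = _sample_parents(A.members, args.nA, args.replace_A, rng)
    for a in parents_A:
        if selfing:
            mates = [a] * args.nB_per_A
        elif within:
            candidates = [m for m in pool_B.members if m is not a] \
                if pool_B.n > 1 else pool_B.members
            mates = _sample_parents(candidates, args.nB_per_A, args.replace_B, rng)
        else:
            mates = _sample_parents(pool_B.members, args.nB_per_A,
                                    args.replace_B, rng)
        for b in mates:
            for _ in range(args.n_per_mate):
                offspring.append(_make_offspring(sim, a, b, rng))

    r = args.ratio_malefemale
    if r is False or r is None or float(r) == 0.0:
        return Cohort(sim, offspring)
    males, females = _assign_sexes(offspring, float(r))
    return Cohort(sim, males), Cohort(sim, females)


def mate_from_pedigree(path, sim: Simulation, rng=None) -> Cohort:
    """Simulate gene dropping down a user-supplied pedigree.

    The CSV has columns ``id,sire,dam`` (0 = unknown). Parents that never
    appear as rows, and 0-coded parents, are instantiated as fresh
    Bernoulli founders. Rows may reference later rows: individuals are
    created in topological order, and the returned cohort follows the
    file's row order.
    """
    rng = sim.rng if rng is None else rng
    if isinstance(path, pd.DataFrame):
        ped = path.copy()
    else:
        ped = pd.read_csv(Path(path), comment="#")
    ped.columns = [c.strip().lower() for c in ped.columns]
    if not {"id", "sire", "dam"}.issubset(ped.columns):
        raise FormatError("pedigree file needs id, sire, dam columns")
    ids = ped["id"].tolist()
    if len(set(ids)) != len(ids):
        raise FormatError("an individual is listed twice in the pedigree")
    rows = {row.id: (row.sire, row.dam) for row in ped.itertuples()}

    built: dict = {}

    def build(pid, trail):
        if pid in built:
            return built[pid]
        if pid == 0 or pid not in rows:
            # Unknown or unlisted parent: a fresh Bernoulli founder.
            ind = sim._new_founder(sim._bernoulli_haplotypes((2, sim.genome.n_loci)))
        else:
            if pid in trail:
                raise ValidationError(f"pedigree cycle involving id {pid!r}")
            s, d = rows[pid]
            sire = build(s, trail | {pid}) if s != 0 else build(0, trail)
            dam = build(d, trail | {pid}) if d != 0 else build(0, trail)
            gametes = (form_gamete(sire, sim.genome, rng),
                       form_gamete(dam, sim.genome, rng))
            ind = Individual(sim.new_id(), gametes, sire=sire, dam=dam)
        if pid != 0:
            built[pid] = ind
        return ind

    members = [build(pid, frozenset()) for pid in ids]
    return Cohort(sim, members)


def get_DH(A: Cohort, rng=None) -> Cohort:
    """Doubled haploids: one fresh gamete per parent, duplicated into both
    genome copies, giving a fully homozygous cohort of the same size."""
    sim = A.sim
    rng = sim.rng if rng is None else rng
    members = []
    for parent in A.members:
        g = form_gamete(parent, sim.genome, rng)
        members.append(Individual(sim.new_id(), (g, g), sire=parent, dam=parent))
    return Cohort(sim, members)
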