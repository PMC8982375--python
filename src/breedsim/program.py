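"""Multi-generation breeding programs.

`breed` chains mate() and select() over generations exactly as the
explicit loop would: offspring are produced under the mating arguments,
then the next generation's A-cohort is selected from the male offspring
and the B-cohort from the females (all of them by default). The module
also ships a YAML scenario runner and the two bundled case studies:
rotational crossbreeding among three cattle-like breeds, and a nested
association mapping (NAM) panel built from F1 crosses advanced by
single-seed descent.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, Simulation
from .evaluation import EvaluationSpec, select
from .exceptions import ConfigError, ValidationError
from .genome import build_genome, build_phenome
from .mating import get_DH, mate, mate_from_pedigree

logger = logging.getLogger("breedsim")

__all__ = ["breed", "run_scenario", "run_rotational_cross", "run_nam_panel",
           "load_scenario", "bundled_scenario_path"]


def breed(A: Cohort, B: Cohort | None = None, *, n_gens: int = 1,
          n_select_A: int | None = None, n_select_B="all",
          n_select: int | None = None, rng=None, **args):
    """Repeated mate-then-select over ``n_gens`` generations.

    Remaining keyword arguments are the union of mating arguments (nA,
    nB_per_A, replace_*, n_per_mate, ratio_malefemale, scheme) and
    selection arguments (criteria, methods, weights, ...). With a sexed
    mating (truthy ratio_malefemale) each generation selects
    ``n_select_A`` males as the next A and ``n_select_B`` females
    (default "all") as the next B, and a (males, females) cohort pair is
    returned. An unsexed/single-cohort program instead selects
    ``n_select`` (or ``n_select_A``) offspring as the next A and returns
    one cohort.
    """
    if n_gens < 1:
        raise ValidationError("n_gens must be at least 1")
    rng = A.sim.rng if rng is None else rng
    sexed = bool(args.get("ratio_malefemale"))
    if n_select is None:
        n_select = n_select_A
    for _ in range(n_gens):
        out = mate(A, B, rng=rng, **args)
        if sexed:
            males, females = out
            A = select(males, n_select_A, rng=rng, **args) \
                if n_select_A is not None else males
            B = females if n_select_B in ("all", None) \
                else select(females, int(n_select_B), rng=rng, **args)
        else:
            A = select(out, n_select, rng=rng, **args) \
                if n_select is not None else out
            B = None
    return (A, B) if sexed else A


# ---------------------------------------------------------------------------
# Bundled case studies
# ---------------------------------------------------------------------------

def _base_population(sim: Simulation, founder_n: int, burn_in: int,
                     bottleneck_n: int, post_bottleneck: int,
                     log: list | None = None) -> Cohort:
    """Founders in linkage/Hardy-Weinberg equilibria, random-mated for
    ``burn_in`` generations, bottlenecked, and random-mated again to
    build up linkage disequilibrium."""
    parents = sim.founders(founder_n)
    for g in range(burn_in):
        parents = mate(parents)
        _log_generation(log, f"burn_in_{g + 1}", parents)
    for g in range(post_bottleneck):
        parents = mate(parents[1:bottleneck_n])
        _log_generation(log, f"post_bottleneck_{g + 1}", parents)
    return parents


def run_rotational_cross(seed=None, *, n_chr: int = 1, n_loci: int = 100,
                         founder_n: int = 1500, burn_in: int = 1000,
                         bottleneck_n: int = 100, post_bottleneck: int = 15,
                         purebred_gens: int = 10, n_rotations: int = 3,
                         log: list | None = None) -> dict:
    """Rotational crossbreeding among three breeds (A small, B and C large).

    A base population is random-mated, bottlenecked, and split into three
    pure breeds kept by random selection (breed A: 50 sires x 10 dams
    each x 2 offspring; breeds B and C: 100 sires x 20 dams x 2). The
    rotation then cycles the sire breed B -> A -> C over first-cross
    females while the purebred nuclei continue. Counts are independent of
    the burn-in length. Returns the named cohorts plus the crossbred
    (males, females) of each rotation round.
    """
    genome = build_genome(n_chr=n_chr, n_loci=n_loci)
    phenome = build_phenome(genome, max(1, min(30, genome.n_loci // 2)),
                            vg=1.0, h2=0.5, seed=seed)
    sim = Simulation(genome, phenome, seed=seed)

    parents = _base_population(sim, founder_n, burn_in, bottleneck_n,
                               post_bottleneck, log)
    sires_base = dams_base = parents

    args_A = dict(nA=50, nB_per_A=10, n_per_mate=2, replace_B=True,
                  ratio_malefemale=1, criteria="random",
                  n_gens=purebred_gens, n_select_A=50, n_select_B=500)
    args_BC = dict(nA=100, nB_per_A=20, n_per_mate=2, replace_B=True,
                   ratio_malefemale=1, criteria="random",
                   n_gens=purebred_gens, n_select_A=100, n_select_B=2000)
    sires_A, dams_A = breed(sires_base, dams_base, **args_A)
    sires_B, dams_B = breed(sires_base, dams_base, **args_BC)
    sires_C, dams_C = breed(sires_base, dams_base, **args_BC)
    _log_generation(log, "breed_A", sires_A + dams_A)
    _log_generation(log, "breed_B", sires_B + dams_B)
    _log_generation(log, "breed_C", sires_C + dams_C)

    args_XA = dict(nA=50, nB_per_A=20, n_per_mate=2, replace_B=True,
                   ratio_malefemale=1)
    args_XBC = dict(nA=100, nB_per_A=10, n_per_mate=2, replace_B=True,
                    ratio_malefemale=1)
    args_A1 = {**args_A, "n_gens": 1}
    args_BC1 = {**args_BC, "n_gens": 1}

    # Rotation of the crossbred sire breed: B, then A, then C, then B, ...
    crosses = []
    cross_females = dams_C
    sire_pool = {"A": (sires_A, dams_A), "B": (sires_B, dams_B),
                 "C": (sires_C, dams_C)}
    rotation = ["B", "A", "C"]
    for r in range(n_rotations):
        breed_code = rotation[r % 3]
        cross_args = args_XA if breed_code == "A" else args_XBC
        males_x, females_x = mate(sire_pool[breed_code][0], cross_females,
                                  **cross_args)
        crosses.append((males_x, females_x))
        _log_generation(log, f"rotation_G{r + 1}", males_x + females_x)
        cross_females = females_x
        # Purebred nuclei advance one generation in parallel.
        for code, pure_args in (("A", args_A1), ("B", args_BC1), ("C", args_BC1)):
            sire_pool[code] = breed(*sire_pool[code], **pure_args)

    return {"sires_A": sire_pool["A"][0], "dams_A": sire_pool["A"][1],
            "sires_B": sire_pool["B"][0], "dams_B": sire_pool["B"][1],
            "sires_C": sire_pool["C"][0], "dams_C": sire_pool["C"][1],
            "crosses": crosses, "sim": sim}


def run_nam_panel(seed=None, *, n_chr: int = 1, n_loci: int = 300,
                  n_qtl: int = 30, n_founders: int = 26,
                  n_rils_per_family: int = 200, ssd_gens: int = 4,
                  ssd_per_mate: int = 10, log: list | None = None) -> dict:
    """Nested association mapping panel by F1 crosses + single-seed descent.

    One common parent is crossed to each of the remaining founders to
    give one F1 per family; each F1 is selfed into an F2 of
    ``n_rils_per_family`` seeds, and every seed is advanced by
    ``ssd_gens`` generations of selfing, keeping the top-phenotype
    offspring of each line (the mating/selection settings printed for
    the design), to yield near-homozygous recombinant inbred lines.
    """
    genome = build_genome(n_chr=n_chr, n_loci=n_loci)
    phenome = build_phenome(genome, n_qtl, vg=1.0, h2=0.5, seed=seed)
    sim = Simulation(genome, phenome, seed=seed)

    founders = sim.founders(n_founders)
    common_parent = founders[1]
    diverse_parents = founders[2:n_founders]

    F1 = sim.founders(0)
    for parent in diverse_parents:
        F1 += common_parent * parent
    _log_generation(log, "F1", F1)

    ssd_args = dict(n_per_mate=ssd_per_mate, scheme="selfing",
                    criteria="phenotypes", n_gens=ssd_gens, n_select=1)
    NAM = sim.founders(0)
    families = []
    for family in F1:
        F2 = mate(family, n_per_mate=n_rils_per_family, scheme="selfing")
        rils = sim.founders(0)
        for seed_plant in F2:
            rils += breed(seed_plant, **ssd_args)
        families.append(rils)
        NAM += rils
    _log_generation(log, "NAM", NAM)
    return {"NAM": NAM, "families": families, "F1": F1, "sim": sim}


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------

def bundled_scenario_path(name: str) -> Path:
    """Path of a scenario shipped with the package (e.g. "rotational_cross")."""
    p = Path(__file__).parent / "scenarios" / f"{name}.yml"
    if not p.exists():
        raise ConfigError(f"no bundled scenario named {name!r}")
    return p


def load_scenario(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: scenario must be a mapping")
    return cfg


def _log_generation(log: list | None, label: str, cohort: Cohort):
    if log is None:
        return
    entry = {"step": label, "n": cohort.n}
    if cohort.sim.phenome is not None and cohort.n:
        bv = cohort.get_BVs()
        for t in range(bv.shape[1]):
            entry[f"mean_bv_{t + 1}"] = float(bv[:, t].mean())
            entry[f"var_bv_{t + 1}"] = float(bv[:, t].var())
    log.append(entry)


def _mating_selection_args(d: dict) -> dict:
    allowed = {"nA", "nB_per_A", "replace_A", "replace_B", "n_per_mate",
               "ratio_malefemale", "scheme", "criteria", "methods", "weights",
               "pi", "chain_length", "burn_in",
               "n_gens", "n_select", "n_select_A", "n_select_B"}
    bad = set(d) - allowed
    if bad:
        raise ConfigError(f"unknown argument(s) {sorted(bad)}")
    return d


def run_scenario(config, outdir, seed=None) -> dict:
    """Execute a declarative scenario and write its outputs.

    ``config`` is a path to a YAML file or an equivalent dict with keys:

    - ``seed`` (overridden by the ``seed`` argument when given);
    - ``case_study`` + ``params``: run a bundled case study
      ("rotational_cross" or "nam_panel"); or
    - ``genome`` / ``phenome`` (quick-start parameters or ``{map: path}``)
      and ``steps``: a list of operations, each a mapping with an ``op``
      key among founders, mate, mate_pedigree, select, breed, dh,
      subset, concat, sample, repeat, save. Cohorts are named through
      ``out``/``a``/``b`` keys.

    Writes per-cohort CSVs for every ``save`` step and a
    ``generations.csv`` log of cohort sizes and mean/variance of
    breeding values after every cohort-producing step. Returns the final
    named-cohort namespace plus the log.
    """
    if not isinstance(config, dict):
        config = load_scenario(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed") if seed is None else seed
    log: list[dict] = []

    if "case_study" in config:
        name = config["case_study"]
        params = config.get("params") or {}
        if name == "rotational_cross":
            result = run_rotational_cross(seed=seed, log=log, **params)
        elif name == "nam_panel":
            result = run_nam_panel(seed=seed, log=log, **params)
        else:
            raise ConfigError(f"unknown case study {name!r}")
        _write_log(log, outdir)
        for key, val in result.items():
            if isinstance(val, Cohort):
                val.get_summary(outdir, prefix=key)
        return {"cohorts": result, "log": log}

    gcfg = dict(config.get("genome") or {})
    if not gcfg:
        raise ConfigError("scenario needs a 'genome' section (or a case_study)")
    genome = build_genome(gcfg.pop("map")) if "map" in gcfg \
        else build_genome(**gcfg)
    pcfg = dict(config.get("phenome") or {})
    phenome = None
    if pcfg:
        src = pcfg.pop("map", None) or pcfg.pop("n_qtl", None)
        if src is None:
            raise ConfigError("phenome section needs 'n_qtl' or 'map'")
        phenome = build_phenome(genome, src, seed=seed, **pcfg)
    sim = Simulation(genome, phenome, seed=seed)
    ns: dict[str, Cohort] = {}

    def fetch(name):
        if name not in ns:
            raise ConfigError(f"unknown cohort {name!r}")
        return ns[name]

    def store(out, value):
        if isinstance(value, tuple):
            if not (isinstance(out, (list, tuple)) and len(out) == 2):
                raise ConfigError("sexed matings need two output names")
            ns[out[0]], ns[out[1]] = value
            _log_generation(log, f"{out[0]}|{out[1]}", value[0] + value[1])
        else:
            if not isinstance(out, str):
                raise ConfigError("'out' must name a single cohort here")
            ns[out] = value
            _log_generation(log, out, value)

    def run_steps(steps):
        for step in steps:
            if not isinstance(step, dict) or "op" not in step:
                raise ConfigError(f"each step needs an 'op' key: {step!r}")
            step = dict(step)
            op = step.pop("op")
            if op == "repeat":
                times = int(step.pop("times"))
                inner = step.pop("steps")
                for _ in range(times):
                    run_steps(inner)
            elif op == "founders":
                out = step.pop("out")
                src = step.pop("file", None) or step.pop("n", 0)
                store(out, sim.founders(src))
            elif op == "mate":
                out = step.pop("out")
                a = fetch(step.pop("a"))
                b = fetch(step.pop("b")) if "b" in step else None
                store(out, mate(a, b, **_mating_selection_args(step)))
            elif op == "mate_pedigree":
                out = step.pop("out")
                store(out, mate_from_pedigree(step.pop("file"), sim))
            elif op == "select":
                out = step.pop("out")
                a = fetch(step.pop("a"))
                n = int(step.pop("n"))
                store(out, select(a, n, **_mating_selection_args(step)))
            elif op == "breed":
                out = step.pop("out")
                a = fetch(step.pop("a"))
                b = fetch(step.pop("b")) if "b" in step else None
                store(out, breed(a, b, **_mating_selection_args(step)))
            elif op == "dh":
                store(step.pop("out"), get_DH(fetch(step.pop("a"))))
            elif op == "subset":
                out = step.pop("out")
                lo, hi = step.pop("range")
                store(out, fetch(step.pop("a"))[int(lo):int(hi)])
            elif op == "sample":
                out = step.pop("out")
                a = fetch(step.pop("a"))
                store(out, a.sample(int(step.pop("n")),
                                    replace=bool(step.pop("replace", False))))
            elif op == "concat":
                parts = [fetch(nm) for nm in step.pop("of")]
                total = parts[0]
                for p in parts[1:]:
                    total = total + p
                store(step.pop("out"), total)
            elif op == "save":
                a = fetch(step.pop("a"))
                prefix = step.pop("prefix", "cohort")
                a.get_summary(outdir, prefix=prefix)
                pd.DataFrame(a.get_genotypes()).to_csv(
                    outdir / f"{prefix}_genotypes.csv", index=False, header=False)
            else:
                raise ConfigError(f"unknown step op {op!r}")

    run_steps(config.get("steps") or [])
    _write_log(log, outdir)
    return {"cohorts": ns, "log": log, "sim": sim}


def _write_log(log: list[dict], outdir: Path):
    cols = ["step", "n"]
    extra = sorted({k for e in log for k in e} - set(cols))
    pd.DataFrame(log, columns=cols + extra).to_csv(
        outdir / "generations.csv", index=False)
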