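"""Phenotype simulation, relationship matrices, genetic evaluation
(PBLUP / GBLUP / BayesC), and selection.

Phenotypes are the true breeding value plus a multivariate-normal
residual with the phenome's residual covariance. Evaluation solves the
single-trait mixed-model equations with an overall mean per trait, using
either the pedigree numerator relationship matrix A (tabular method) or
the VanRaden genomic relationship matrix G; BayesC estimates marker
effects by single-site Gibbs sampling with a point mass at zero.
Variance components default to the phenome's true values. Multi-trait
selection combines per-trait criteria through a weighted index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, _index_scores
from .exceptions import NotImplementedMethodError, ValidationError

__all__ = [
    "EvaluationSpec",
    "simulate_phenotypes",
    "compute_A",
    "compute_G",
    "solve_blup",
    "bayesc",
    "genetic_evaluation",
    "select",
]

_RIDGE = 1e-8
_KNOWN_UNSUPPORTED = ("ssBLUP", "single-step", "NN", "neural network",
                      "BayesA", "BayesB", "BayesL", "RR-BLUP")


@dataclass
class EvaluationSpec:
    """Selection/evaluation settings.

    criteria : "phenotypes" (mass selection, default) | "EBV" | "random"
    methods : "GBLUP" | "PBLUP" | "BayesC" (used when criteria = "EBV")
    weights : per-trait selection-index weights (default all 1; negative
        weights select in the opposite direction for that trait)
    vg, ve : variance components for the mixed model; default to the
        phenome's true values
    pi : BayesC prior probability that a marker has zero effect
    chain_length, burn_in : BayesC Gibbs chain settings
    """

    criteria: str = "phenotypes"
    methods: str = "GBLUP"
    weights: np.ndarray | None = None
    vg: np.ndarray | None = None
    ve: np.ndarray | None = None
    pi: float = 0.95
    chain_length: int = 2000
    burn_in: int = 500

    def validate(self, n_traits: int):
        if self.criteria not in ("phenotypes", "EBV", "random"):
            raise ValidationError(f"unknown selection criteria {self.criteria!r}")
        if not 0.0 <= self.pi <= 1.0:
            raise ValidationError("pi must lie in [0, 1]")
        if self.chain_length <= self.burn_in:
            raise ValidationError("chain_length must exceed burn_in")
        if self.weights is not None and np.asarray(self.weights).size != n_traits:
            raise ValidationError("weights length must equal the number of traits")

    @classmethod
    def from_kwargs(cls, **kwargs) -> "EvaluationSpec":
        own = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in kwargs.items() if k in own})


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(A: Cohort, rng=None, force: bool = False) -> np.ndarray:
    """Observed phenotypes y = BV + e, e ~ N(0, ve), per individual.

    Values are sticky: an individual keeps its first drawn phenotype
    (repeatability one) unless ``force=True`` re-simulates everyone.
    """
    sim = A.sim
    if sim.phenome is None:
        raise ValidationError("phenotypes require a phenome")
    rng = sim.rng if rng is None else rng
    ve = sim.phenome.ve
    t = sim.phenome.n_traits
    out = np.empty((A.n, t))
    todo = [m for m in A.members if force or m.phenotypes is None]
    if todo:
        e = rng.multivariate_normal(np.zeros(t), ve, size=len(todo),
                                    method="cholesky") if np.any(ve) \
            else np.zeros((len(todo), t))
        for m, ei in zip(todo, e):
            m.phenotypes = m.breeding_values(sim) + ei
    for i, m in enumerate(A.members):
        out[i] = m.phenotypes
    return out


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

def compute_A(pedigree: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    ``pedigree`` has columns id, sire, dam with ancestors before
    offspring; 0 marks an unknown parent (assumed unrelated,
    non-inbred). A_ij = (A_{j,s(i)} + A_{j,d(i)}) / 2 and
    A_ii = 1 + A_{s(i),d(i)} / 2.
    """
    ids = pedigree["id"].to_numpy()
    pos = {int(v): i for i, v in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, row in enumerate(pedigree.itertuples()):
        s, d = int(row.sire), int(row.dam)
        for p in (s, d):
            if p != 0 and (p not in pos or pos[p] >= i):
                raise ValidationError(
                    f"pedigree not ancestors-first: parent {p} of {row.id}")
        si = pos.get(s, -1) if s != 0 else -1
        di = pos.get(d, -1) if d != 0 else -1
        if i:
            a_s = A[si, :i] if si >= 0 else 0.0
            a_d = A[di, :i] if di >= 0 else 0.0
            A[i, :i] = A[:i, i] = 0.5 * (a_s + a_d)
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return A


def compute_G(M: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    Z = M - 2p column-centers the dosage matrix; G = Z Z' / (2 sum_j
    p_j (1 - p_j)). Frequencies default to those observed in ``M``;
    monomorphic loci contribute nothing, but at least one polymorphic
    locus is required.
    """
    M = np.asarray(M, dtype=float)
    if p is None:
        p = M.mean(axis=0) / 2.0
    p = np.asarray(p, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValidationError("all loci are monomorphic; G is undefined")
    Z = M - 2.0 * p
    return (Z @ Z.T) / denom


# ---------------------------------------------------------------------------
# Mixed-model equations and BayesC
# ---------------------------------------------------------------------------

def solve_blup(y: np.ndarray, K: np.ndarray, vg: float, ve: float,
               obs_index: np.ndarray | None = None) -> np.ndarray:
    """Single-trait BLUP of breeding values from the mixed-model equations.

    Model: y = 1 mu + Z u + e with u ~ N(0, K vg), e ~ N(0, I ve).
    ``K`` may cover more individuals than are phenotyped; ``obs_index``
    maps records to rows of K (identity by default). Returns u-hat for
    every individual in K.
    """
    if vg <= 0:
        raise ValidationError("genetic variance must be positive")
    if ve < 0:
        raise ValidationError("residual variance cannot be negative")
    y = np.asarray(y, dtype=float).ravel()
    q = K.shape[0]
    n = y.size
    obs = np.arange(n) if obs_index is None else np.asarray(obs_index)
    lam = ve / vg if ve > 0 else _RIDGE
    Kinv = np.linalg.inv(K + _RIDGE * np.eye(q))

    Z = np.zeros((n, q))
    Z[np.arange(n), obs] = 1.0
    top = np.concatenate([[n], Z.sum(axis=0)])
    lower = np.concatenate([Z.sum(axis=0)[:, None], Z.T @ Z + lam * Kinv], axis=1)
    lhs = np.vstack([top, lower])
    rhs = np.concatenate([[y.sum()], Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[1:]


def bayesc(M: np.ndarray, y: np.ndarray, *, pi: float = 0.95,
           chain_length: int = 2000, burn_in: int = 500,
           vg: float = 1.0, ve: float = 1.0, rng=None):
    """BayesC marker-effect model by single-site Gibbs sampling.

    Each marker effect is zero with prior probability ``pi`` and
    otherwise normal with a common variance carrying a scaled-inverse
    chi-square prior (scale set from ``vg``, the expected number of
    nonzero markers and the observed heterozygosity); the residual
    variance has a scaled-inverse chi-square prior around ``ve``. ``pi``
    is held fixed.

    Returns
    -------
    dict with posterior means: ``effects`` (per marker), ``mu``,
    ``inclusion`` (posterior inclusion frequency per marker), and
    ``ebv = M @ effects``.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not 0.0 <= pi <= 1.0:
        raise ValidationError("pi must lie in [0, 1]")
    if chain_length <= burn_in:
        raise ValidationError("chain_length must exceed burn_in")
    M = np.asarray(M, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = M.shape

    if pi >= 1.0:
        mu = y.mean()
        return {"effects": np.zeros(m), "mu": mu,
                "inclusion": np.zeros(m), "ebv": np.full(n, 0.0)}

    pobs = np.clip(M.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
    sum2pq = float(np.sum(2.0 * pobs * (1.0 - pobs)))
    nu_b, nu_e = 4.0, 4.0
    # Prior mode of the marker-effect variance from the genetic variance
    # spread over the markers expected to be in the model.
    var_b0 = max(vg / max((1.0 - pi) * sum2pq, 1e-12), 1e-12)
    S_b = var_b0 * (nu_b - 2.0) / nu_b
    S_e = max(ve, 1e-12) * (nu_e - 2.0) / nu_e

    mtm = np.einsum("ij,ij->j", M, M)
    beta = np.zeros(m)
    delta = np.zeros(m, dtype=bool)
    mu = y.mean()
    resid = y - mu
    var_b, var_e = var_b0, max(ve, 1e-8)
    log_prior_ratio = np.log(1.0 - pi) - np.log(pi) if pi > 0 else np.inf

    sum_beta = np.zeros(m)
    sum_incl = np.zeros(m)
    sum_mu = 0.0
    kept = 0
    for it in range(chain_length):
        # Overall mean.
        resid += mu
        mu = resid.mean() + rng.normal(0.0, np.sqrt(var_e / n))
        resid -= mu
        # Marker effects, one site at a time.
        for j in range(m):
            mj = M[:, j]
            if beta[j] != 0.0:
                resid += mj * beta[j]
            rhs = mj @ resid
            c = mtm[j] + var_e / var_b
            # log Bayes factor of delta_j = 1 vs 0 (effect integrated out).
            logBF = 0.5 * (rhs * rhs / (c * var_e)
                           - np.log(mtm[j] * var_b / var_e + 1.0))
            if pi == 0.0:
                incl = True
            else:
                u = logBF + log_prior_ratio
                incl = rng.random() < 1.0 / (1.0 + np.exp(-u))
            if incl:
                mean_j = rhs / c
                beta[j] = rng.normal(mean_j, np.sqrt(var_e / c))
                resid -= mj * beta[j]
                delta[j] = True
            else:
                beta[j] = 0.0
                delta[j] = False
        # Common marker-effect variance (scaled-inverse chi-square posterior).
        k = int(delta.sum())
        var_b = (beta[delta] @ beta[delta] + nu_b * S_b) / \
            rng.chisquare(nu_b + k)
        # Residual variance.
        var_e = (resid @ resid + nu_e * S_e) / rng.chisquare(nu_e + n)
        if it >= burn_in:
            sum_beta += beta
            sum_incl += delta
            sum_mu += mu
            kept += 1
    effects = sum_beta / kept
    return {"effects": effects, "mu": sum_mu / kept,
            "inclusion": sum_incl / kept, "ebv": M @ effects}


# ---------------------------------------------------------------------------
# Evaluation and selection
# ---------------------------------------------------------------------------

def genetic_evaluation(A: Cohort, spec: EvaluationSpec | None = None,
                       rng=None, **kwargs) -> np.ndarray:
    """Estimate breeding values for a cohort and store them on its members.

    Phenotypes are simulated (or reused, being sticky) for every
    candidate; the configured method then runs per trait with that
    trait's variance components (multi-trait analyses are per-trait
    models combined later by the selection index). Returns the
    (n, n_traits) EBV matrix.
    """
    sim = A.sim
    if sim.phenome is None:
        raise ValidationError("genetic evaluation requires a phenome")
    spec = EvaluationSpec.from_kwargs(**kwargs) if spec is None else spec
    spec.validate(sim.phenome.n_traits)
    rng = sim.rng if rng is None else rng
    vg = sim.phenome.vg if spec.vg is None else np.atleast_2d(spec.vg)
    ve = sim.phenome.ve if spec.ve is None else np.atleast_2d(spec.ve)
    y = simulate_phenotypes(A, rng=rng)
    t = sim.phenome.n_traits

    method = spec.methods
    if method in ("GBLUP", "PBLUP"):
        if method == "GBLUP":
            K = compute_G(A.get_genotypes(rng=rng))
            obs = None
            take = slice(None)
        else:
            ped = A.get_pedigree(ancestors=True)
            K = compute_A(ped)
            pos = {int(v): i for i, v in enumerate(ped["id"])}
            obs = np.array([pos[m.id] for m in A.members])
            take = obs
        ebv = np.empty((A.n, t))
        for trait in range(t):
            u = solve_blup(y[:, trait], K, float(vg[trait, trait]),
                           float(ve[trait, trait]), obs_index=obs)
            ebv[:, trait] = u[take]
    elif method == "BayesC":
        M = A.get_genotypes(rng=rng).astype(float)
        ebv = np.empty((A.n, t))
        for trait in range(t):
            fit = bayesc(M, y[:, trait], pi=spec.pi,
                         chain_length=spec.chain_length, burn_in=spec.burn_in,
                         vg=float(vg[trait, trait]), ve=float(ve[trait, trait]),
                         rng=rng)
            ebv[:, trait] = fit["ebv"]
    elif any(method.lower() == k.lower() for k in _KNOWN_UNSUPPORTED):
        raise NotImplementedMethodError(
            f"evaluation method {method!r} is recognized but not implemented")
    else:
        raise ValidationError(f"unknown evaluation method {method!r}")

    for i, member in enumerate(A.members):
        member.ebv = ebv[i]
    return ebv


def select(A: Cohort, n: int, *, criteria="phenotypes", methods="GBLUP",
           weights=None, rng=None, spec: EvaluationSpec | None = None,
           **kwargs) -> Cohort:
    """Select ``n`` individuals from a cohort.

    - ``criteria="phenotypes"`` (mass selection, the default): rank by
      the weighted phenotype index, descending;
    - ``criteria="EBV"``: run the configured genetic evaluation on the
      candidates, then rank the weighted EBV index;
    - ``criteria="random"``: uniform sample without replacement.

    Negative weights select in ascending order of that trait. Ties are
    broken by id (oldest first). The order of the returned cohort is the
    ranking order.
    """
    sim = A.sim
    rng = sim.rng if rng is None else rng
    if n > A.n:
        raise ValidationError(f"cannot select {n} from a cohort of {A.n}")
    if spec is None:
        spec = EvaluationSpec.from_kwargs(criteria=criteria, methods=methods,
                                          weights=weights, **kwargs)
    if sim.phenome is not None:
        spec.validate(sim.phenome.n_traits)

    if spec.criteria == "random":
        idx = rng.permutation(A.n)[:n]
        return Cohort(sim, [A.members[i] for i in idx])
    if spec.criteria == "phenotypes":
        values = simulate_phenotypes(A, rng=rng)
    else:  # EBV
        values = genetic_evaluation(A, spec=spec, rng=rng)
    scores = _index_scores(A, values, spec.weights)
    order = np.lexsort((A.ids, -scores))
    return Cohort(sim, [A.members[i] for i in order[:n]])
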