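"""Genome and phenome construction.

The genome is a map of biallelic loci: chromosome code, genetic position
(cM), optional physical position (bp), and minor allele frequency (MAF).
The phenome attaches allele-substitution effects (QTL) to those loci
together with genetic/residual covariance matrices and heritabilities.

Quick-start constructors place loci uniformly on 1-Morgan chromosomes and
draw standard-normal QTL effects that are then rescaled so the expected
Hardy-Weinberg genetic covariance matches the requested ``vg`` exactly.
"""

from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger("breedsim")

MISSING_CODES = (-1, 9)

__all__ = [
    "GenomeMap",
    "Phenome",
    "parse_map_file",
    "write_map_file",
    "build_genome",
    "build_phenome",
]


def _natural_key(code: str):
    """Sort key treating embedded integers numerically ('2' < '10', '1A' < '1B')."""
    return tuple(int(tok) if tok.isdigit() else tok
                 for tok in re.split(r"(\d+)", str(code)) if tok != "")


class GenomeMap:
    """Ordered biallelic loci grouped by chromosome.

    Parameters
    ----------
    chrom_of : sequence of str
        Chromosome code per locus. Codes with letter suffixes ("1A", "1B")
        are distinct chromosomes (subgenomes segregate independently).
    cM : array-like of float
        Genetic position per locus in centimorgans, nonnegative.
    bp : array-like of int, optional
        Physical position per locus in base pairs.
    maf : array-like of float, optional
        Minor allele frequency per locus in [0, 0.5]; defaults to 0.5.
    lengths_morgan : mapping or float, optional
        Chromosome genetic length in Morgans. By default the larger of
        1 Morgan and max(cM)/100 on each chromosome.
    mutation_rate : float
        Per-locus, per-meiosis allele-flip probability (default 0).
    genotyping_error_rate : float
        Per-call probability that a reported dosage is perturbed
        (default 0). Errors affect outputs only, never inheritance.
    """

    def __init__(self, chrom_of, cM, bp=None, maf=None, *, lengths_morgan=None,
                 mutation_rate=0.0, genotyping_error_rate=0.0):
        chrom_of = np.asarray([str(c) for c in chrom_of], dtype=object)
        cM = np.asarray(cM, dtype=float)
        n = cM.size
        if chrom_of.size != n:
            raise ValidationError("chromosome codes and cM positions differ in length")
        if n == 0:
            raise ValidationError("a genome needs at least one locus")
        if np.any(cM < 0):
            raise ValidationError("genetic positions must be nonnegative")
        if bp is not None:
            bp = np.asarray(bp, dtype=np.int64)
            if np.any(bp < 0):
                raise ValidationError("physical positions must be nonnegative")
        if maf is None:
            maf = np.full(n, 0.5)
        else:
            maf = np.asarray(maf, dtype=float)
            if np.any((maf < 0) | (maf > 0.5)):
                raise ValidationError("maf values must lie in [0, 0.5]")
        if not 0 <= mutation_rate <= 1 or not 0 <= genotyping_error_rate <= 1:
            raise ValidationError("rates must be probabilities in [0, 1]")

        # Canonical locus order: chromosomes in natural code order, loci by
        # (cM, bp) within a chromosome — invariant under input row shuffles.
        self.chrom_codes: list[str] = sorted(set(chrom_of.tolist()), key=_natural_key)
        chrom_index = {c: i for i, c in enumerate(self.chrom_codes)}
        ci = np.array([chrom_index[c] for c in chrom_of])
        bp_key = bp if bp is not None else np.zeros(n, dtype=np.int64)
        order = np.lexsort((bp_key, cM, ci))
        self.locus_chrom = ci[order]
        self.cM = cM[order]
        self.bp = bp[order] if bp is not None else None
        self.maf = maf[order]
        self._order = order  # original-row -> canonical mapping (for callers)

        self.n_chr = len(self.chrom_codes)
        self.n_loci = n
        self.mutation_rate = float(mutation_rate)
        self.genotyping_error_rate = float(genotyping_error_rate)

        # Per-chromosome contiguous slices into the canonical locus arrays.
        starts = np.searchsorted(self.locus_chrom, np.arange(self.n_chr))
        ends = np.searchsorted(self.locus_chrom, np.arange(self.n_chr), side="right")
        self.chrom_slices = [slice(int(s), int(e)) for s, e in zip(starts, ends)]

        max_cM = np.array([self.cM[sl].max() if sl.stop > sl.start else 0.0
                           for sl in self.chrom_slices])
        if lengths_morgan is None:
            self.lengths_morgan = np.maximum(max_cM / 100.0, 1.0)
        elif np.isscalar(lengths_morgan):
            self.lengths_morgan = np.full(self.n_chr, float(lengths_morgan))
        else:
            self.lengths_morgan = np.array(
                [float(lengths_morgan[c]) for c in self.chrom_codes])
        if np.any(self.lengths_morgan * 100.0 < max_cM - 1e-9):
            raise ValidationError("chromosome length shorter than its furthest locus")

    @property
    def hwe_weights(self) -> np.ndarray:
        """Per-locus Hardy-Weinberg dosage variance 2 p (1 - p)."""
        return 2.0 * self.maf * (1.0 - self.maf)

    def __repr__(self):
        return (f"GenomeMap(n_chr={self.n_chr}, n_loci={self.n_loci}, "
                f"lengths_morgan={np.round(self.lengths_morgan, 3).tolist()})")


class Phenome:
    """QTL effects plus trait (co)variance structure.

    Attributes
    ----------
    effects : ndarray, shape (n_loci, n_traits)
        Allele-substitution effect of each locus on each trait (0 for
        non-QTL loci).
    vg, ve : ndarray, shape (n_traits, n_traits)
        Genetic and residual covariance matrices.
    h2 : ndarray, shape (n_traits,)
        Narrow-sense heritabilities, ``vg_tt / (vg_tt + ve_tt)``.
    """

    def __init__(self, effects: np.ndarray, vg: np.ndarray, ve: np.ndarray):
        self.effects = np.asarray(effects, dtype=float)
        if self.effects.ndim != 2:
            raise ValidationError("effects must be a loci x traits matrix")
        self.n_traits = self.effects.shape[1]
        self.vg = np.asarray(vg, dtype=float).reshape(self.n_traits, self.n_traits)
        self.ve = np.asarray(ve, dtype=float).reshape(self.n_traits, self.n_traits)
        for name, m in (("vg", self.vg), ("ve", self.ve)):
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValidationError(f"{name} must be symmetric")
            if np.any(np.diag(m) < 0):
                raise ValidationError(f"{name} must have nonnegative diagonal")
        denom = np.diag(self.vg) + np.diag(self.ve)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.h2 = np.where(denom > 0, np.diag(self.vg) / denom, 0.0)

    @property
    def qtl_indices(self) -> list[np.ndarray]:
        """Indices of loci with a nonzero effect, per trait."""
        return [np.flatnonzero(self.effects[:, t]) for t in range(self.n_traits)]

    def __repr__(self):
        return (f"Phenome(n_traits={self.n_traits}, "
                f"h2={np.round(self.h2, 3).tolist()})")


# ---------------------------------------------------------------------------
# Map-file I/O
# ---------------------------------------------------------------------------

def parse_map_file(path):
    """Read a map CSV into a :class:`GenomeMap` plus optional effect columns.

    The dialect is a comma-separated file with a header; ``#``-prefixed
    lines are comments. Recognized columns: ``chr`` (required), ``cM``
    and/or ``bp`` (at least one required), ``maf`` (optional, default
    0.5), and any number of ``eff_``-prefixed trait-effect columns.

    Returns
    -------
    (GenomeMap, ndarray or None)
        The genome and, when ``eff_*`` columns are present, an
        (n_loci, n_traits) effect matrix aligned to the canonical locus
        order of the returned genome.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    if "chr" not in df.columns:
        raise FormatError(f"{path}: map file must contain a 'chr' column")
    has_cM, has_bp = "cM" in df.columns, "bp" in df.columns
    if not (has_cM or has_bp):
        raise FormatError(f"{path}: map file needs a 'cM' or a 'bp' column")

    required = [c for c in ("cM", "bp") if c in df.columns]
    numeric = df[required].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.warning("%s: dropping %d rows with non-numeric positions",
                       path, int(bad.sum()))
        df = df.loc[~bad]
        numeric = numeric.loc[~bad]
    if df.empty:
        raise FormatError(f"{path}: no parseable loci")
    df = df.assign(**{c: numeric[c] for c in required})

    bp = df["bp"].to_numpy(np.int64) if has_bp else None
    maf = pd.to_numeric(df["maf"], errors="coerce").fillna(0.5).to_numpy() \
        if "maf" in df.columns else None
    if has_cM:
        cM = df["cM"].to_numpy(float)
    else:
        # Genetic positions absent: infer linearly from bp within each
        # chromosome, anchored at the endpoints of a 1-Morgan chromosome.
        cM = np.empty(len(df), dtype=float)
        for _, idx in df.groupby("chr").groups.items():
            b = df.loc[idx, "bp"].to_numpy(float)
            span = b.max()
            cM[df.index.get_indexer(idx)] = (b / span * 100.0) if span > 0 else 0.0

    genome = GenomeMap(df["chr"].tolist(), cM, bp=bp, maf=maf)

    eff_cols = [c for c in df.columns if c.startswith("eff_")]
    effects = None
    if eff_cols:
        eff_cols = sorted(eff_cols, key=_natural_key)
        effects = df[eff_cols].apply(pd.to_numeric, errors="coerce")
        if effects.isna().any().any():
            raise FormatError(f"{path}: non-numeric values in effect columns")
        effects = effects.to_numpy(float)[genome._order]
    return genome, effects


def write_map_file(genome: GenomeMap, path, effects: np.ndarray | None = None):
    """Serialize a genome (and optional effect columns) back to map CSV."""
    cols = {"chr": [genome.chrom_codes[c] for c in genome.locus_chrom],
            "cM": genome.cM}
    if genome.bp is not None:
        cols["bp"] = genome.bp
    cols["maf"] = genome.maf
    df = pd.DataFrame(cols)
    if effects is not None:
        effects = np.atleast_2d(np.asarray(effects, dtype=float))
        if effects.shape[0] != genome.n_loci:
            effects = effects.T
        for t in range(effects.shape[1]):
            df[f"eff_{t + 1}"] = effects[:, t]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def build_genome(source=None, *, n_chr=None, n_loci=None, maf=0.5,
                 mutation_rate=0.0, genotyping_error_rate=0.0,
                 species=None) -> GenomeMap:
    """Build a genome from a map file or quick-start parameters.

    Quick start (``n_chr``, ``n_loci``) places ``n_loci`` loci uniformly
    along each of ``n_chr`` chromosomes of 1 Morgan, every locus at the
    supplied ``maf`` (scalar or per-locus array, default 0.5).

    Parameters
    ----------
    source : path-like, optional
        Map CSV (see :func:`parse_map_file`). When the file carries only
        ``bp`` positions, genetic positions are inferred linearly over a
        1-Morgan chromosome.
    n_chr, n_loci : int
        Quick-start shape: ``n_loci`` is loci PER chromosome.
    species : str, optional
        Preloaded reference maps are not bundled; a supplied species is
        ignored with a warning and quick-start/file defaults apply.
    """
    if species is not None:
        msg = (f"species='{species}' requested but reference maps are not "
               "bundled; falling back to default 1-Morgan linear maps")
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    if source is not None:
        genome, _ = parse_map_file(source)
        genome.mutation_rate = float(mutation_rate)
        genome.genotyping_error_rate = float(genotyping_error_rate)
        return genome

    if n_chr is None or n_loci is None:
        raise ValidationError("quick start requires n_chr and n_loci")
    if n_chr < 1 or n_loci < 1:
        raise ValidationError("n_chr and n_loci must be at least 1")
    # Uniform spacing, endpoints anchored at 0 and 100 cM (1 Morgan).
    pos = np.linspace(0.0, 100.0, n_loci) if n_loci > 1 else np.array([50.0])
    cM = np.tile(pos, n_chr)
    chrom_of = np.repeat([str(c + 1) for c in range(n_chr)], n_loci)
    maf_arr = np.broadcast_to(np.asarray(maf, dtype=float), cM.shape).copy()
    return GenomeMap(chrom_of, cM, maf=maf_arr, lengths_morgan=1.0,
                     mutation_rate=mutation_rate,
                     genotyping_error_rate=genotyping_error_rate)


# ---------------------------------------------------------------------------
# Phenome construction
# ---------------------------------------------------------------------------

def _as_cov(vg, t):
    vg = np.asarray(vg, dtype=float)
    if vg.ndim == 0:
        return np.eye(t) * float(vg), False
    if vg.ndim == 1:
        if vg.size != t:
            raise ValidationError("per-trait vg length mismatch")
        return np.diag(vg), False
    if vg.shape != (t, t):
        raise ValidationError("vg matrix shape mismatch")
    return vg, True


def _chol_pd(m, name):
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        raise ValidationError(f"{name} must be symmetric positive definite") from None


def build_phenome(genome: GenomeMap, source, *, vg=None, h2=0.5, ve=None,
                  rng=None, seed=None) -> Phenome:
    """Build a phenome from QTL counts, an effect matrix, or a map file.

    Parameters
    ----------
    genome : GenomeMap
    source : int | sequence of int | ndarray | path-like
        Quick start: number of QTL per trait (scalar = one trait). QTL
        positions are drawn uniformly without replacement per trait and
        raw effects from a standard normal. Alternatively an explicit
        (n_loci, n_traits) effect matrix, or a map CSV whose ``eff_*``
        columns supply it.
    vg : scalar, vector or matrix, optional
        Target genetic covariance. Quick-start effects are rescaled so
        the Hardy-Weinberg expectation sum_j 2 p_j (1-p_j) a_jt a_js
        reproduces ``vg`` exactly; a full matrix imposes the covariance
        through its Cholesky factor on the standardized effect columns.
        When an effect matrix is supplied and ``vg`` is omitted, the
        effects are taken at face value and ``vg`` is their implied
        Hardy-Weinberg covariance.
    h2 : scalar or per-trait, in (0, 1)
        Used to derive residual variances ``ve_tt = vg_tt (1-h2)/h2``
        when ``ve`` is not given; residuals are uncorrelated by default.
    ve : matrix, optional
        Residual covariance; overrides ``h2`` (heritabilities are then
        recomputed from vg and ve).
    """
    rng = np.random.default_rng(seed) if rng is None else rng

    effects = None
    if isinstance(source, (str, Path)):
        _, effects = parse_map_file(source)
        if effects is None:
            raise FormatError(f"{source}: no eff_* columns for the phenome")
    elif isinstance(source, np.ndarray) and source.ndim == 2:
        effects = np.array(source, dtype=float)
    elif isinstance(source, pd.DataFrame):
        effects = source.to_numpy(float)

    if effects is not None:
        if effects.shape[0] != genome.n_loci:
            raise ValidationError("effect matrix must have one row per locus")
        n_traits = effects.shape[1]
        raw = effects
    else:
        n_qtl = np.atleast_1d(np.asarray(source, dtype=int))
        n_traits = n_qtl.size
        if np.any(n_qtl < 1):
            raise ValidationError("each trait needs at least one QTL")
        if np.any(n_qtl > genome.n_loci):
            raise ValidationError("n_qtl cannot exceed the number of loci")
        raw = np.zeros((genome.n_loci, n_traits))
        for t in range(n_traits):
            # Independent QTL set per trait; coincidences across traits are
            # allowed (pleiotropy by collision).
            idx = rng.choice(genome.n_loci, size=n_qtl[t], replace=False)
            raw[idx, t] = rng.standard_normal(n_qtl[t])

    h2 = np.broadcast_to(np.asarray(h2, dtype=float), (n_traits,)).copy()
    if ve is None and np.any((h2 <= 0) | (h2 >= 1)):
        raise ValidationError("heritabilities must lie strictly in (0, 1)")

    w = genome.hwe_weights
    if vg is None and effects is not None:
        final = raw
        vg_mat = final.T @ (w[:, None] * final)
    else:
        if vg is None:
            vg = 1.0
        vg_mat, full = _as_cov(vg, n_traits)
        if not np.allclose(vg_mat, vg_mat.T, atol=1e-10):
            raise ValidationError("vg must be symmetric")
        if full:
            # Standardize columns to unit HWE covariance (Gram factor of the
            # weighted cross-product), then impose vg via its Cholesky factor.
            L = _chol_pd(vg_mat, "vg")
            C = raw.T @ (w[:, None] * raw)
            M = _chol_pd(C, "the raw-effect Gram matrix")
            std = np.linalg.solve(M, raw.T).T      # std' W std = I
            final = std @ L.T
        else:
            var = np.einsum("j,jt,jt->t", w, raw, raw)
            if np.any(var <= 0):
                raise ValidationError("a trait has zero expected genetic variance")
            final = raw * np.sqrt(np.diag(vg_mat) / var)

    if ve is None:
        ve_mat = np.diag(np.diag(vg_mat) * (1.0 - h2) / h2)
    else:
        ve_mat, _ = _as_cov(ve, n_traits)
    return Phenome(final, vg_mat, ve_mat)
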