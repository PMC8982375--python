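# Methods

## Inheritance model

`breedsim` simulates Mendelian inheritance with founder-origin segment
lists ("gene dropping by descent"). Every founder contributes two
haplotypes to a pool of explicit 0/1 allele vectors; each chromosome
copy of any descendant is an ordered list of half-open intervals
`[start_cM, next_start_cM)` tagged with the founder haplotype they
descend from. One meiosis per chromosome:

1. draw a crossover count from Poisson(L), L the map length in Morgans
   (1 Morgan = 1 expected crossover, no interference, no obligate
   chiasma);
2. place the breakpoints i.i.d. uniformly on (0, 100·L) cM;
3. pick the starting parental copy with probability ½ and splice the two
   parental segment lists at the breakpoints, merging adjacent segments
   of equal origin.

A crossover falling exactly on a locus position assigns that locus to
the downstream (new-origin) segment — the half-open convention. Allele
states are realized lazily: each locus copies the allele of the founder
haplotype whose segment covers its genetic position. Recombination hot
and cold spots arise solely from nonuniform locus spacing on the genetic
map; interference models and sex-specific maps are out of scope. De-novo
mutations (per-locus, per-meiosis probability `mutation_rate`, default
0) are stored as exception lists on the gamete and applied at
realization, so founder haplotypes and the compact representation are
never altered.

The segment engine's correctness oracle is naive per-locus inheritance:
given identical crossovers and coin flips, realized genotypes must be
bit-identical to dropping every allele explicitly. The suite enforces
this on 3-generation pedigrees, and separately checks that realized
identity-by-descent over 10,000 pedigree drops reproduces the tabular
numerator relationship matrix within ±0.02.

## Genome and phenome

A genome is declared from a map CSV (`chr`, `cM`, `bp`, `maf`, optional
`eff_*` columns; `#` comments; missing codes −1/9 in all CSV inputs) or
by quick start. Choices where the interface left room:

- Loci are canonically ordered by chromosome (natural code order, so
  "2" < "10" and "1A" ≠ "1B" — subgenomes of allopolyploids segregate as
  independent chromosomes) and by cM (then bp) within a chromosome;
  parsing is therefore invariant to input row order. Rows whose position
  fields fail to parse are dropped with a warning.
- Chromosome length defaults to 1 Morgan; with cM data it is
  max(cM)/100, never shorter than the furthest locus. A file with only
  `bp` gets genetic positions by endpoint-anchored linear interpolation
  onto a 1-Morgan chromosome. Preloaded species maps are not bundled; a
  `species` argument falls back to these defaults with a warning.
- Quick start places `n_loci` loci per chromosome uniformly with both
  endpoints on the map (0 and 100 cM); absent MAF defaults to 0.5;
  mutation and genotyping-error rates default to 0.

Quick-start QTL: per trait, positions are drawn uniformly without
replacement and raw effects from a standard normal. Distinct traits draw
independent QTL sets; coincidences (pleiotropy by collision) are
allowed. With a full target matrix `vg`, the raw effect columns are
first orthonormalized under the Hardy–Weinberg weights
w_j = 2 p_j (1 − p_j) (Cholesky factor of the weighted Gram matrix) and
then multiplied by the Cholesky factor of `vg`, so the expected HWE
genetic covariance Σ_j w_j α_jt α_js equals `vg` *exactly*, even when
QTL sets overlap; cross-trait covariance is necessarily carried by loci
in the union of the sets. With a scalar/diagonal `vg` only per-column
rescaling is applied. User-supplied effect files are taken at face value
when `vg` is omitted (`vg` is then their implied HWE covariance) —
rescaling a user's effects without being asked would be surprising.
Residuals default to uncorrelated, ve_tt = vg_tt(1 − h²_t)/h²_t with h²
required strictly inside (0, 1); an explicit `ve` overrides `h2` and
heritabilities are recomputed. Because scaling uses map MAFs rather than
a realized founder cohort (the phenome exists before any founders),
realized var(BV)/var(y) converges to h² stochastically; at 10,000
founders it sits well within ±0.03.

## Founders and cohorts

Count-based founders draw each allele Bernoulli(1 − MAF) — linkage and
Hardy–Weinberg equilibria; allele 1 is the reference allele, so its
frequency is 1 − MAF. LD must be generated the way a breeder would, by
random mating (the rotational scenario's burn-in does exactly this).
Haplotype files use columns (2j−1, 2j) as the paternal/maternal alleles
of locus j; genotype files are phased by fair coin at heterozygous
loci; missing entries are imputed by the Bernoulli rule.

Cohorts are ordered views: the algebra (`+`, 1-based inclusive
subsetting, `sample`, `sort`, `*`) shares Individual objects and never
copies or mutates them. Phenotypes are sticky — drawn once per
individual and reused — which makes repeated selection reproducible; an
explicit re-simulation flag exists. True BV is the effect matrix times
the error-free dosage; genotyping errors (per-call probability, uniform
re-draw among the other two dosages) perturb only reported genotype
matrices, never inheritance or true BV. Ids increase in creation order,
so sorting by id is always ancestors-first and `sort(by="pedigree")`
is oldest-to-youngest.

## Mating

All schemes parameterize one loop — `nA` common parents from A, each
with `nB_per_A` mates from B, `n_per_mate` offspring per pair — so the
offspring count is exactly nA·nB_per_A·n_per_mate. Defaults reproduce
random mating (every member of A once, one mate, one offspring);
"diallel cross" presets nA=|A|, nB_per_A=|B|; "selfing" mates each
selected parent with itself. Single-cohort `mate(A)` random-mates within
A and excludes self-pairing whenever |A| > 1 (selfing is its own
scheme). Sampling without replacement uses a seeded shuffle of the
cohort's current order. Sexing under `ratio_malefemale = r` is
deterministic: exactly round(total·r/(1+r)) males, interleaved through
the offspring sequence (a Bresenham pattern), so scheme counts are exact
and reproducible rather than binomially noisy. Pedigree-driven mating
instantiates unknown or unlisted parents as fresh Bernoulli founders and
builds individuals in topological order regardless of row order; ovum
pick-up is just `mate(dams, sires, nA=..., nB_per_A=...)`; doubled
haploids duplicate one fresh gamete per parent, giving a same-size,
fully homozygous cohort.

## Evaluation and selection

Phenotypes: y = BV + e, e ~ N(0, V_E). Evaluation defaults to the
phenome's true variance components — REML/Bayesian component estimation
is out of scope, and this isolates the breeding-scheme comparison from
estimation noise. PBLUP builds the tabular A over the candidates plus
all reachable ancestors and solves the mixed-model equations with
records on candidates only; GBLUP uses VanRaden's G with frequencies
from the evaluated cohort (a 1e−8 ridge guards singular kernels).
Multi-trait evaluation is per-trait models combined by the weighted
selection index (weights default to 1; negative weights reverse the
direction for that trait), not a Kronecker multi-trait system — a
deliberate simplification documented here. BayesC runs single-site
Gibbs with π the prior probability that a marker has *zero* effect
(π = 1 therefore returns all-zero effects), a common marker-effect
variance with a scaled-inverse-χ² prior (ν = 4, scale from vg spread
over the markers expected in the model), fixed π, chain 2,000 with
burn-in 500 by default. Selection on phenotypes/EBV ranks the index
descending with ties broken by id; EBV selection evaluates only the
candidate cohort (no historical pooling). Recognized but unsupported
method names (single-step, neural networks, other Bayesian alphabet
members) raise a dedicated not-implemented error to keep the interface
honest.

`breed()` is literally the mate-then-select loop: with sexed matings the
next A is `n_select_A` males and the next B defaults to **all** females
(the conventional equivalence loop keeps every dam); given the same
seed it is bit-identical to writing the loop out, which the suite
asserts.

## Bundled case studies and scenarios

- `rotational_cross`: 1,500 founders random-mated (default burn-in
  1,000 generations), bottlenecked to 100 with 15 further generations to
  extend LD, split into breed A (50 sires × 10 dams × 2 offspring,
  random selection, 50♂/500♀ kept) and breeds B, C (100 × 20 × 2,
  100♂/2,000♀ kept) over 10 generations, then a 3-round rotation of the
  crossbred sire breed B → A → C with 2,000 first-cross offspring per
  round while the purebred nuclei advance in parallel.
- `nam_panel`: 26 founders, one common parent crossed to the other 25;
  each F1 selfed into 200 F2 seeds; each seed advanced 4 further selfing
  generations keeping the top-phenotype offspring of 10 per line
  (the printed design's settings; classical single-seed descent would
  advance a random seed — with one seed kept either way the
  homozygosity trajectory is identical). After the 5 selfing meioses
  from F1, heterozygosity is (½)⁵ ≈ 3% of the founder level; the suite
  checks < 0.05 absolute.

The scenario runner executes a YAML step list (founders / mate /
mate_pedigree / select / breed / dh / subset / sample / concat / repeat
/ save) with one global seed, logging n and mean/variance of BV per
cohort-producing step to `generations.csv` and writing pedigree /
BV / phenotype / genotype CSVs on `save`.

## Problem sizes and determinism

All randomness flows through one `numpy.random.Generator` per
`Simulation` (public entry points accept an override), so fixed seeds
make entire programs bit-reproducible. The test and acceptance profiles
use genomes of 100–500 loci on 1–2 chromosomes, founder cohorts of
10,000 for variance-ratio checks (Monte-Carlo error ≈ 0.01–0.015 on a
heritability), 10,000 meioses for crossover moments, and a 50-generation
burn-in for the rotational scenario — the cohort counts checked there
are independent of burn-in length, which only deepens LD. The full
printed burn-in (1,000 generations) is the scenario default.

## What the generator does and does not emulate

Founder populations are ideal: unlinked (LD only via subsequent
mating), Hardy–Weinberg, biallelic, with user-specified frequencies.
Real data's ascertainment bias, genotyping batch structure, map errors,
selection signatures, and overlapping generations are not modeled, so
passing tests demonstrate the simulator's internal consistency and its
agreement with quantitative-genetic expectations — not calibration to
any particular livestock or crop population. Other known limits:
diploids only (allopolyploidy only via lettered subgenome codes),
per-trait rather than truly multivariate mixed models, true variance
components assumed known, no age structure or economic indices, and
ancestry references retain the full pedigree in memory, which grows
linearly with generations simulated.
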