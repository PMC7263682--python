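# Methods

This note documents the models behind `bpsim`, the defaults and units of the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic populations used in the test suite do
and do not show about real data.

## Genome and storage model

A genome is a list of chromosomes with marker positions in Morgan on 0-based
half-open coordinates `[0, L)`. When markers are placed automatically, marker
`i` of `n` sits at `(i + 0.5)·L/n`, so no marker coincides with a chromosome
boundary and terminal segments never have zero recombination distance to a
marker. Imported PLINK maps are interpreted as centiMorgan and divided
by 100; the chromosome length of an imported map is the last marker position
plus a fixed 1e-6 Morgan margin (there is no canonical terminal rule for a
map file). VCF sites without a `CM` INFO field are converted at 1 cM/Mb, the
usual rough mammalian average; this is logged and should be overridden with
real genetic positions whenever available.

Founder haplotypes are stored bit-packed, two rows per founder, one bit per
marker. Every non-founder gamete is represented by, per chromosome, an array
of segment end positions and the founder haplotype row each segment copies,
plus a list of de-novo mutation marks (global marker indices whose allele is
flipped). Segments are resolved to founder coordinates *eagerly* when the
gamete is created, by composing the parent-relative crossover mosaic with the
parent's own segments. The alternative — storing parent-relative breakpoints
and resolving lazily at derivation time — is externally indistinguishable;
eager resolution was chosen because it makes allele derivation a single
segment-array lookup independent of pedigree depth. The raw meiosis record
(crossover positions, starting gamete, de-novo marks) is retained alongside:
it is small, it allows re-basing (below), and it gives the test suite an
independent eager-haplotype derivation path to compare against.

Mutation marks are copied into child segments at creation, so a flip applies
to every descendant inheriting the covering segment; a second hit at the same
marker cancels (recurrent-flip semantics on a fixed marker panel — no new
sites arise).

**Re-basing.** `rebase_founders(pop, g)` materializes the haplotypes of
generation `g` into the founder store, collapses those individuals' mosaics
to single self-referencing segments, drops their parent links, and recomposes
all later generations from the stored meiosis records. Genotypes of every
retained individual are bit-identical before and after (tested), and segment
counts of descendants can only shrink. This is only worthwhile for very deep
simulations; the breeding-scale scenarios here never need it.

## Meiosis

Haldane model: the number of crossovers on a chromosome of length `L` Morgan
is Poisson(`scale · L`), positions are i.i.d. uniform, there is no
interference and no obligate chiasma. `scale` is a per-sex map multiplier
(default 1.0 for both sexes); the paternal gamete of a mating uses the male
scale, the maternal the female scale. The starting parental gamete of each
chromosome is a fair coin, independent across chromosomes. The per-marker
per-meiosis mutation rate defaults to 0 (no documented default exists for
this class of simulation; a fixed panel with zero recurrent mutation is the
cleanest baseline) and is configurable per action.

## Traits

Additive QTL take genotype values `(0, a, 2a)` with `a ~ N(0, 1)`; dominant
QTL take `(0, d, a)` with complete dominance `d = a` by default and a
`dominance_degree` knob for partial dominance; epistatic terms are explicit
value grids over joint dosages (3×3 for pairs). The sampling distributions
are deliberately simple and documented rather than canonical — there is no
standard for them — and can be replaced by constructing `QTL` /
`EpistaticTerm` objects directly. Multi-trait architectures are pleiotropic:
each QTL's per-trait effect vector is drawn from N(0, C) through a Cholesky
root of the genetic correlation matrix C.

After sampling, effects are affine-rescaled on the *realized* founder cohort
so that founder TBV has mean exactly 0 and population variance (ddof = 0)
exactly `var_target` per trait. Scaling on the realized distribution rather
than the Hardy–Weinberg expectation makes the gain unit — founder genomic
standard deviations — exact rather than approximate, at the price of tying
the unit to the founder sample. Re-applying the scaling is a no-op. Traits
without QTL have TBV ≡ 0 and are pure-noise phenotypes.

Phenotypes at heritability h² are `y = TBV + e`, `e ~ N(0, σ²_e)` with
`σ²_e = var_target · (1 − h²)/h²`; `n` repeated observations are averaged
and stored with their count, giving an effective residual variance
`σ²_e / n` in the evaluation. h² = 0 is rejected (undefined residual).

## Genetic evaluation

Pedigree **A** uses the tabular method over the ancestor closure, founders
unrelated and non-inbred. **G** is VanRaden's first method with reference
allele frequencies fixed at the empirical founder-generation frequencies for
the whole scenario, so G stays on one scale across generations; monomorphic
markers are excluded from centering and denominator. Single-step **H**
replaces the genotyped block of A by `τ·G_adj + (1−τ)·A₂₂` (τ = 0.95), where
`G_adj` matches G to A₂₂ on mean diagonal and mean off-diagonal, and
propagates the change through `A₁₂A₂₂⁻¹`.

The GBLUP solver assumes *known* heritability: λ = (1−h²)/h², intercept-only
fixed effects (μ̂ by GLS), observation counts as residual weights, and a
blended `K* = 0.99·K + 0.01·I` for invertibility (a standard, documented
constant; with K = I it is exact, so the closed-form checks hold to 1e-10).
Prediction for unphenotyped candidates propagates through `K_QP K_PP⁻¹`.
Variance-component estimation (REML/Bayesian) is out of scope by design;
externally estimated EBVs can be inserted via `insert_ebv` and are used by
selection verbatim.

## Selection, mating, orchestration

Truncation selection ranks a weighted sum of per-trait criterion values,
breaking ties by ascending id so results are independent of candidate order.
Optimum genetic contributions maximize `c′ĝ` subject to `c′K*c ≤ θ`, per-sex
sums of 1/2 and `c ≥ 0`, solved in Lagrangian closed form on the active set
with iterative truncation of negative contributions; the whole program is
defined on the blended K* so the quadratic constraint is always well posed,
and a general SLSQP solve of the same program is used as a test oracle.
θ = ∞ degenerates to all mass on the best candidate per sex.

Default mating is uniform random with replacement: each of the `n` offspring
draws its sire and dam independently and uniformly. Under this scheme two
random offspring share a sire with probability `1/N_m`, which is what makes
the expected kinship increase analytic (below). `balanced` mating assigns
usage counts proportional to contributions by largest-remainder rounding.
Offspring sexes are deterministic floor/ceil of the sex ratio, assigned
alternately at 50/50 so cohort counts are exact, males first otherwise.

A breeding action executes phenotyping → evaluation → selection → mating →
offspring creation → cost booking, each step optional. Every stochastic step
draws from its own named stream spawned from the master seed (founders,
traits, phenotypes, meiosis, selection), so a scenario is bit-reproducible
from one integer and running the steps as separate actions equals running
them jointly. Scenario configs are plain JSON dicts validated by
`validate_config`; replicate `r` runs at seed `master + r`.

## Kinship convention

Coancestry f(i, j) is the probability that one allele sampled uniformly from
the genome of i and one from j at the same uniform position descend from the
same founder allele. It is computed exactly by length-weighted founder-
segment overlap (a locus-sampling estimator is the fallback for populations
whose ancestry was discarded by re-basing). The *reported* kinship is
f/2: a non-inbred self-kinship is then 0.25 and a parent-offspring or
full-sib pair has expectation 0.125. This factor-of-two convention is kept
explicit and configurable because both conventions circulate; the plain
coancestry is always returned alongside. Under it, the expected offspring-
cohort kinship after one round of random mating with replacement from
`N_m` sires and `N_f` dams of unrelated founders is
`(1/4)(1/(2N_m) + 1/(2N_f))/2` — 0.00625 for 20/20 and 0.015625 for 5/20 —
which the segment-overlap computation reproduces.

Parent–offspring kinship is exactly 1/8 for *every* meiosis realization
(the offspring's parental gamete is a mosaic of the parent's two gametes, so
the IBD probability is 1/4 regardless of crossover placement); full-sib
kinship varies around 1/8 with segregation. Both are tested.

## Problem sizes and what the tests show

The flagship check runs the two-scenario truncation-selection experiment —
100 founders (50M/50F), 10,000 SNPs on 5 × 2 Morgan chromosomes, 50 additive
+ 10 dominant QTL scaled to variance 1, phenotypes at h² = 0.5, GBLUP EBVs
from VanRaden G, 20♂/20♀ vs 5♂/20♀ selected, 100 offspring — at 500
replicates per scenario, a size chosen so the Monte-Carlo standard error of
the mean gain (≈ 0.008 SD units) is well below the differences of interest
while a full run stays in the minutes range on one core. Statistical tests
use 3·SE tolerances at stated draw counts throughout.

Synthetic founders are sampled marker-independently: per-marker allele
frequencies are drawn from U(0, 1) by default (the conventional "runif"
default for internally sampled base populations) and haplotypes are
independent Bernoulli draws. This emulates an outbred, unstructured,
linkage-equilibrium base population. Real populations carry LD, relatedness
and site-frequency spectra shaped by demography; none of that is generated
here (founders can instead be imported from VCF or PLINK files, e.g. out of
a coalescent simulator). Consequently, passing tests validate the machinery
— storage, meiosis, evaluation, selection accounting — and the
linkage-equilibrium baseline, not the realism of any particular species'
genome.

## Numerical choices and degenerate inputs

- Ties in selection break by ascending id; selection output is invariant
  under candidate permutation.
- GBLUP blending constant 0.01; OGC and GBLUP share it.
- Founder TBV scaling uses population variance (ddof 0) of the founder
  cohort; a zero-variance trait is centered only.
- Zero-length chromosomes yield no crossovers; empty selectors default to
  the last generation; empty candidate groups raise named errors.
- Multi-allelic VCF sites are skipped with a warning; missing genotypes are
  an error; unphased heterozygotes get a seeded random phase.
- Segment composition merges adjacent segments copying the same founder row,
  so segment counts measure effective recombination history.

## Known limitations

- No crossover interference, gene conversion, or structural variation.
- No X/Y-specific inheritance, polyploidy, or overlapping-generation age
  structure beyond gen/cohort/database addressing.
- Intercept-only fixed effects in GBLUP; single-trait evaluation per solve.
- No mate-allocation optimization; contributions control usage counts only.
- The founder-SD gain unit is tied to the realized founder cohort; very
  small founder populations make it a noisy unit.
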