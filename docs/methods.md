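# Methods

This note documents the models implemented in `strandspectra`, the
conventions and defaults they use, and what the synthetic-data generator
does and does not emulate.

## Fluctuation analysis

A fluctuation assay grows many parallel cultures from small inocula and
plates each on selective medium. Mutations arise at random during
exponential growth, so a culture's resistant-colony count r is the sum of
clone sizes of the mutational events it happened to accumulate: the
heavy-tailed Luria–Delbrück distribution. Two classical estimators of m,
the expected number of mutational events per culture, are implemented:

* **Method of the median.** m solves r̃/m − ln m = 1.24, where r̃ is the
  median count. The left side is strictly decreasing in m, so the root is
  unique; it is found with Brent's method to a residual below 1e−9.
  For an even number of cultures the *lower* median is used (this affects
  r̃ discretely; the convention is fixed and documented rather than
  interpolated, since counts are integers).
* **p0 method.** m = −ln(fraction of cultures with zero mutants).
  Preferred automatically when the median count is zero; an error directs
  the caller from one estimator to the other outside its domain.

The rate per locus per generation is μ = m/N, with N the number of cells
at plating divided by the plating fraction (the correction is applied to
N, not to the counts). A `per_division` flag switches to the μ = m/2N
convention; default off. Rates are carried on the ×10⁻⁷ scale that
reporter-gene rate tables conventionally print.

**Confidence intervals.** The published tables give 95% CIs without a
stated method and without raw counts, so the package uses a
distribution-free construction: exact binomial(n, ½) order-statistic
bounds on the median count, transformed through the median estimator (or,
for the p0 method, the Clopper–Pearson interval on the zero fraction
transformed through −ln). This is reproducible without distributional
assumptions; it is *not* expected to reproduce any particular published
interval. Below five cultures the bounds fall back to the extreme order
statistics with a warning. Simulation shows ≥90% empirical coverage at
nominal 0.95 for 30-culture experiments at m = 2 (asserted in the test
suite).

The median method is known to carry a few-percent bias that grows with m
(at m ≈ 6.5 it under-estimates by ~13%); experiments aiming at precise
rates should keep m in roughly 0.5–5.

## Mutation spectra and rates

Events are classified from ref/alt strings: single-base substitutions
(transition when both bases are purines or both pyrimidines, transversion
otherwise), single-base insertions/deletions, and complex (anything
longer). Classification, coordinates (1-based, coding strand, inclusive
spans) and ref-against-reference validation happen at read time.

Class and site rates use the standard reporter bookkeeping

    rate = (events / isolates sequenced) × overall locus rate.

The denominator is the number of independent isolates sequenced, not the
total number of mutations: the two differ when isolates carry several
mutations, and the published worked class rates only reproduce with the
isolate denominator. An isolate carrying two events at one site
contributes two to that site's count, consistently with this choice.

Single-base indels inside a homopolymer run cannot be localized within
the run, so they are pooled over the run's full span (e.g. 757–760) and
keyed by operation and base (`delG`, `insA`). Substitutions are never
pooled.

A site with zero observed events gets the **one-event bound**
(1/isolates) × overall rate, flagged `is_bound` and conventionally
printed with '<'. A **hotspot** is a site whose rate is ≥10-fold the
wild-type rate at the same site; a wild-type site with no events uses the
one-event bound as denominator, which is conservative (the true fold can
only be larger). The threshold is inclusive. No significance testing or
multiplicity correction is layered on the fold rule.

When comparing the two reporter orientations, the site set is the union
of hotspot sites of both strains (or of all observed sites when no
wild-type baseline is supplied); a side with zero events contributes its
one-event bound and the fold ratio is flagged as a lower bound.

## Strand assignment

Replication of the reporter starts at a nearby origin and traverses the
gene once; the coding-strand end nearest the origin (`fork_entry`) fixes
the geometry. The leading strand is synthesized in the direction of fork
movement, so its template is the strand read 3′→5′ along that direction:
fork entry at the coding 5′ end makes the noncoding strand the leading
template; entry at the 3′ end swaps the roles. Inverting the gene
(orientation OR1 ↔ OR2) flips `fork_entry` and hence every strand role —
derived from geometry, not a lookup table.

A substitution X→Y on the coding strand admits two mechanistic
explanations: misinsertion of complement(Y) opposite template X on the
coding strand, or misinsertion of Y opposite template complement(X) on
the noncoding strand. Under a dNTP pool imbalance, candidates whose
misinserted nucleotide is in the excess set E survive; a unique survivor
names the template strand and hence the nascent strand that made the
error. Because complementation swaps purines and pyrimidines, a strictly
pyrimidine (or strictly purine) excess set assigns all 12 substitution
types uniquely — asserted by enumeration against a brute-force oracle.

E is derived from the pool table as {n : fold-over-wt(n) ≥ threshold},
default threshold 5: under the studied imbalance (dCTP ~26×, dTTP ~14×,
dATP ~2×, dGTP ~1×) this yields E = {C, T} and is robust to anything in
(2, 14]. Mismatch-extension context (purine tracts downstream) is
reported in the call's rationale but is deliberately *not* a decision
rule — the mechanism is qualitative, and using it to break ties would
manufacture certainty. Ambiguity (zero or two surviving candidates) is a
first-class `unassigned` result, never an error; complex events are
always unassigned.

Single-base indels in homopolymer runs are assigned by the *next
incorporated nucleotide*: for each template strand, the base incorporated
immediately past the run (complement of the coding 5′-flank on the coding
template; the coding base after the run on the noncoding template). A
slipped intermediate is stabilized by rapid extension only when that
nucleotide is in excess; a unique qualifying strand yields the call.
Runs touching a sequence boundary have no next base on one side and that
strand does not qualify. Indels outside any run are unassigned with
rationale "no run context".

## Mismatch-repair correction factors

CF = rate in the MMR-deficient background / rate in the matched
MMR-proficient background, computed with the same class or pooled-site
rates as above. Zero-event sides take the one-event bound and make the
CF an upper bound (deficient side empty) or a lower bound (proficient
side empty); a 0/0 site is reported indeterminate with counts but no
number. Ratios of CFs across backgrounds carry the weaker of the two
bound flags. CF is invariant under common rescaling of both strains'
overall rates (tested).

Recomputing the indel-class CF from the bundled published counts gives
(130/259 × 2236)/(101/173 × 57) ≈ 33.7; the source table prints 32,
presumably from unrounded rates. The package reports the recomputed
value and does not force agreement.

Double-mutant hotspots are classified by which single mutant shares them:
only the MMR-null single → `mmr_driven`; only the pool-imbalanced single
→ `pool_driven`; both → `synergistic`; sites that are not double-mutant
hotspots are excluded.

## Homopolymer runs

Maximal runs are annotated on the coding strand (a G-run and its
complementary C-run are one physical site, reported with the coding
base). Annotation stores all runs ≥2 so thresholds stay analysis-time
choices; the headline indel fraction uses runs ≥3. The run-length/rate
relation fits ln(rate) against length by least squares, aggregating site
rates per length by sum (default) or mean; the mean is appropriate when
the planted per-site rate law itself is being recovered, since the sum
also absorbs the number of runs per length. A single represented length
refuses to fit.

## Synthetic-data generator

The generator replaces the wet-lab inputs so every stage is testable.

**Fluctuation counts.** Deterministic doubling from `n_initial` over
G = round(log₂(n_final/n_initial)) generations — no cell death, no mutant
fitness cost, no pre-existing mutants, i.e. the canonical assumptions the
estimators invert. Mutations per generation are Poisson with mean
rate × cells dividing; a clone founded at generation g contributes
2^(G−g) resistant cells. Defaults: n_initial 1000, n_final ≈ 1.64×10⁷
(N_t ~10⁷, as in a typical assay), 24 cultures, plating fraction 1.
Zero-class frequency e^(−m) and the heavy right tail are asserted as
distributional diagnostics.

**Spectra.** Per-site error propensities encode the mechanistic rules:

* substitutions — base weight 1, ×50 when the strand-specific misinserted
  dNTP is in excess, ×2 per downstream template base (up to 3) whose
  complementary dNTP is in excess (extension bonus), summed over both
  template strands;
* run indels — weight ∝ e^(0.9·L) in run length L, doubled when either
  strand's next-incorporated nucleotide past the run is in excess.

The indel base weight (120) is set so that, with the pyrimidine-excess
pools, single-base indels are roughly half of all events in the
repair-deficient dataset — the class balance observed in the
pool-imbalanced strains, where indels are the dominant class.

MMR is per-category thinning with retention = 1/CF: defaults 1/20 for
substitutions, 1/300 for A:T-run indels, 1/10 for G:C-run indels,
mirroring the observed contrast in which repair of A:T-run slippage is
far more efficient. The deficient dataset samples `n_isolates` isolates
from raw propensities; the proficient dataset samples from thinned
propensities with its overall rate scaled by the expected retained
fraction, so planted CFs are recoverable by construction (a closed test,
not a circular one: recovery goes through the ordinary spectrum/CF code
path and its counting noise). Isolates carry a second mutation with
probability 0.05, reproducing the events > isolates structure of real
tables.

**What is not emulated:** sequence-context fidelity beyond the stated
multipliers, replication timing and checkpoint effects, selection or
fitness differences among mutants, multi-base complex events, and any
site-specific repair variation beyond the three categories. Passing
recovery tests therefore demonstrates correctness of the estimators and
bookkeeping under the stated model, not robustness to real-data
violations of it.

**Fixture locus.** Random ACGT sequence (seeded) with one planted run per
base (A×3, C×4, G×5, T×6, guard-flanked to stay maximal), so repeat
analyses always have support at lengths 3–6.

## Numerical choices and problem sizes

Root finding: Brent on a bracket grown geometrically; residual < 1e−9
asserted. Order-statistic CI indices from the exact binomial CDF. All
randomness flows from a single integer seed through
`numpy.random.default_rng`; generators are bit-reproducible given
(seed, config). Statistical tests use 10⁴ cultures / 10⁴ isolates, sizes
at which binomial noise bands (3σ) are tight enough to detect real
defects while each test runs in seconds; coverage checks use 300
replicate 30-culture experiments.

## Known limitations

* The median estimator's bias at large m is inherited, not corrected; no
  Ma–Sandri–Sarkar maximum-likelihood estimator or partial-plating
  likelihood correction is provided.
* CI methods for published tables whose raw counts were never deposited
  cannot be reproduced; the package's intervals are its own convention.
* Strand assignment names the strand, never the polymerase; inferring
  polymerase identity requires assumptions outside this model.
* Hotspot calling is the bare fold rule; with many sites some calls at
  the threshold will be noise.
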