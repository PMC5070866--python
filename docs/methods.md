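# Methods

This note documents the statistical procedures implemented in
`wmsnorm`, the defaults chosen where the design was open, what the
synthetic-data generator does and does not emulate, and known
limitations.

## Island filtration

**Model.** Under genuine presence of an organism, mapped read starts
are approximately uniform over its genome of length G. For N reads the
expected mean spacing between consecutive starts is close to G/N.
Reads confined to a horizontally transferred island shrink that mean
drastically, so each reference is tested with a one-sample t-test of
the N−1 neighbor spacings against the null mean G/N.

Choices and conventions:

- **One-sided alternative (Δ̄ < G/N).** Clustering can only lower the
  mean neighbor spacing; a two-sided test would spend half its level
  on an impossible direction.
- **No wraparound spacing.** The N−1 forward differences of the sorted
  starts are used; adding a circular gap between the last and first
  read would change the null mean.
- **Zero-variance convention.** A perfectly regular ladder or stack of
  reads has sample SD 0 and no t statistic; p is defined as 0 when the
  mean is below the null (filtered) and 1 otherwise. Degenerate read
  stacks are precisely the pathology the filter exists for.
- **p-value threshold 1e-3** by default. Simulation shows three reads
  inside a 1 kb island of a 3 Mb genome always fall below this
  threshold (with two spacings the t distribution has one degree of
  freedom, and |t| ≥ ~2·(G/N)/island size), so sensitivity extends
  down to minimal island coverage. On uniform reads the test is
  conservative: the measured type-I error is below the nominal level
  at all read counts tried, because spacings are right-skewed and the
  true mean spacing G/(N+1) sits slightly below the null G/N.
- **Minimum 3 reads** (two spacings) to attempt the test; hits with
  fewer reads are classified `too_few_reads` and left in the report.

**Genome-size check.** The same uniform model gives a closed-form size
estimate from the read-start range R = max − min: E[R] = G(N−1)/(N+1),
hence the estimate R(N+1)/(N−1). Since R/G ~ Beta(N−1, 2), an upper
confidence bound at level c (default 0.95) is R / q with
q = Beta(N−1, 2).ppf(1−c), satisfying P(G ≤ R/q) = c. A hit whose
upper bound is below 10% of the actual genome size is filtered; in
10–50% it is flagged *uncertain* and reported with its t statistics
and a spacing histogram for manual review — prior knowledge about the
sample decides such cases. The range estimator was chosen over
alternatives (e.g. spacing-sum estimators) because it is closed-form,
consistent, and its null distribution is exact.

**Short-spacing heuristic.** The fraction of spacings below a
threshold (default 10 bp) is always reported; an upper limit on it is
available but disabled by default, since a sensible limit depends on
coverage depth.

Filtration runs per reference sequence (strain) *before* the
strain-to-species collapse: islands belong to a specific reference,
and a species record aggregates only surviving references.

## GC-bias model

**Observable.** Normalized coverage per integer GC percentage point i,
from 100 bp non-overlapping windows:

    NormCov_i = (Rst_i / W_i) / (Rst_Total / W_Total)        (single genome)
    NormCov_ij = (Rst_ij / W_ij) / ((Rst_Total / m) / W_Totalj)   (pool of m)

The pooled form attributes an equal share of the sample's read starts
to every member, so between-genome over/under-representation caused by
GC bias remains visible in the curves — this is what makes an
equal-DNA calibration pool informative about the bias surface. The
identity Σᵢ NormCov_i·W_i·(Rst_Total/W_Total) = Rst_Total holds
exactly and is enforced by test.

Window conventions (the upstream coverage-metrics tools in this space
do not agree on these; the following are this package's contract):

- tail windows shorter than 100 bp are dropped from W_i; reads
  starting there are excluded from GC counting but retained for
  abundance counting (tracked in a remainder ledger);
- window GC is computed excluding ambiguous bases from numerator and
  denominator; windows more than half ambiguous are dropped;
- GC points are integers by round-half-up of 100·(G+C)/counted;
- read GC is computed on the stored, aligned read sequence.

**Surface.** The fitted family is a Gaussian bell in read GC plus a
cubic polynomial and a logarithmic genome-GC term (coefficients
θ₁..θ₈; see README). The bell captures the central GC preference of
the library chemistry; the cubic absorbs its asymmetries; the negative
log term captures the observed decline of representation with genome
GC, which flattens at high GC. Fitting is ordinary (unweighted)
nonlinear least squares over (bin GC, genome GC, normcov) triples
pooled across genomes; weighting by window support is available as an
option. Observations are bin GC points; predictions are evaluated at
per-read GC — the bin is the only GC resolution available at fit time,
while the read is the unit being weighted.

Numerical choices:

- bins supported by fewer than 5 windows are excluded from the fit
  (their normcov estimates are shot-noise dominated);
- initialization is data-driven (θ₂, θ₃ from the mean/SD of occupied
  GC points, θ₁, θ₄ from the normcov range) with a small deterministic
  multistart over the Gaussian center and width, the only parameters
  whose misplacement produces local minima; the fit is deterministic;
- convergence tolerance 1e-5, at most 50 iterations; non-convergence
  raises with diagnostics — no silent fallback;
- at least two distinct genome GC values are required, otherwise the
  log term is aliased with the intercept;
- predictions are floored at 0.01, capping read weights at 100, so a
  mis-extrapolated corner of the surface cannot let a single read
  dominate a sample.

Residual standard error and degrees of freedom (points − 8) are
reported with every fit and serialized with the coefficients as JSON,
so a model fitted once per sequencing platform can be shipped and
audited.

## Quantification

Multireads are resolved before counting: reads whose best hits span
two or more species are discarded (no proportional redistribution —
with complete references the discarded mass is ambiguous by
construction and redistributing it would import the very biases being
corrected); hits to multiple strains of one species collapse to the
strain with the highest raw count in the sample (ties broken
lexicographically). Each retained read contributes weight
1/NormCov(GC_R, GC_G) to its species; weighted counts are divided by
the representative reference length in Mb. Relative abundances are
percentages of summed per-Mb weighted counts. Absolute load per host
cell multiplies the per-Mb count by 6191.39 (diploid human genome,
Mb) over the host read count; the constant is configurable for
non-human hosts.

RMSE between estimated and true percentage compositions is
sqrt(mean((est − act)²)), in percentage points.

Every input read reconciles to exactly one ledger category — assigned,
discarded-multispecies, removed-with-filtered-hit — with tail-window
exclusions tracked separately for GC counting; the report footer
prints the ledger.

## Synthetic data

The generator emulates the parts of a WMS experiment that the
statistics see:

- genomes as i.i.d. base sequences at a target GC (default ladder
  32.8, 39.7, 50.5, 57.3, 64.9, 66.7, 70.8% — the calibration range —
  at 500 kb for fast runs);
- 75 bp single-end reads whose start windows are drawn with
  probability proportional to the bias surface at (window GC, genome
  GC); a genome's total representation is its DNA proportion times its
  mean window bias, reproducing the overrepresentation of GC-poor
  genomes;
- islands as length-preserving substitutions of a donor segment, with
  clustered reads placed uniformly inside the island;
- pools with exact truth tables (DNA proportions, realized read
  counts, island coordinates).

The default planted surface (θ = (2.0, 45.0, 12.0, 3.6, 0.01, −1e-4,
0.0, −0.8), floor 0.01) peaks near 45% read GC and spans roughly a
five-fold representation range across the genome-GC ladder, matching
the magnitude seen on fragment-library short-read platforms.

What it does **not** emulate: sequencing errors and quality values
(the package consumes alignments, so base-call noise enters only
through the upstream aligner), paired ends, fragment-length and
mappability bias, shared sequence between references (multiread
structure must be constructed explicitly in tests), replication-fork
DNA content, and real genome composition (i.i.d. sequences have
narrower window-GC spreads than real genomes, with their repeats and
islands). Passing tests therefore demonstrate the correctness of the
estimators under the stated model, not platform-specific performance
on real data — for which the bias model must be refitted from real
calibration sequencing.

## Study sizes used by tests and the acceptance script

Calibration: 7 genomes × 500 kb, 70 000 reads, equal DNA. Validation:
8 genomes × 400 kb, 80 000 reads, proportions 20/17/14/12/11/10/9/7%.
Equal genome lengths within each pool make DNA proportions and per-Mb
read shares coincide, so the truth table is comparable to both raw and
normalized estimates without a length confounder; the length
normalization itself is exercised by unit tests with unequal lengths.
These sizes give a few hundred reads per occupied GC bin — enough for
stable curves — and run in seconds.

## Known limitations

- The min-window support filter stands in for outlier-point removal
  before fitting; a formal per-point significance screen is not
  implemented.
- The uncertain band (size upper bound in 10–50% of the actual genome)
  is a reporting convention, not a calibrated decision rule.
- Discarded multispecies reads shrink totals; highly promiscuous
  communities (multiread fractions toward the high end) lose more mass
  and relative estimates then lean on the species-specific remainder.
- The bias model extrapolates outside the calibrated GC range only
  through its functional form; the 0.01 floor bounds, but does not
  remove, extrapolation error.
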