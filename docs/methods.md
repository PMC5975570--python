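# Methods

## The design problem

Planning a two-group RNA-seq differential-expression study requires choosing
the number of biological replicates per group before any data exist.  Each
gene g contributes a read count per sample modelled as negative binomial
(NB) with control-group mean μ_g and dispersion φ_g (variance
μ_g + φ_g μ_g²; √φ_g is the biological coefficient of variation).  Under
the alternative, the treatment group's mean is ρ μ_g, with an optional
normalization ratio ω (geometric mean of normalization factors between the
groups) scaling the treatment side.  Because thousands of genes are tested
at once, the design must control the false discovery rate, not a per-gene
type I error.

## The test and its power

Inference is by the conditional exact test on group totals.  The sum of n
iid NB(μ, φ) counts is NB(nμ, φ/n), so the group totals ("pseudo counts")
are

    y0 ~ NB(n0 μ, φ/n0),    y1 ~ NB(n1 ω ρ μ, φ/n1).

Given the total s = y0 + y1, the two-sided p-value sums the
null-conditional probabilities of all splits of s at most as probable as
the observed one (ties included, with a 1e-7 relative slack so that
mathematically tied splits are never separated by floating-point
rounding — the same convention as R's `binom.test`).  A gene's power at
marginal level α is the alternative-measure mass of the strict rejection
region {p(y1, y0) < α}:

    ε(n, ρ, μ, φ, ω, α) = Σ_{y0} Σ_{y1} f(y1; n1ωρμ, φ/n1) f(y0; n0μ, φ/n0) 1[p(y1,y0) < α],

with each marginal sum truncated at its `trunc_tol` and `1 − trunc_tol` NB
quantiles (default 1e-12; the neglected mass, < 4·trunc_tol, bounds the
power error and is logged at DEBUG level).

### Conditional-law structure

Conditional on s, the null law of the control split a is proportional to
exp(c[a] + d[s−a] + a·δ(s)), where c and d are 1-D tables of the
gamma-function terms of the two null pmfs and the tilt δ(s) carries the
entire dependence on the common per-sample null mean estimate
μ̂ = s/(n0 + n1 ω).  Two consequences we rely on:

- For ω = 1 the tilt vanishes: the test is *independent of how the null
  mean is estimated*, and the conditional law is the beta-binomial
  BB(s, n0/φ, n1/φ).  The common-mean convention above therefore only
  matters for ω ≠ 1, where it is our explicit choice.
- When both size parameters n_i/φ are ≥ 1 the conditional law is
  log-concave, so its two monotone tails can be merged in linear time
  (stable sort of two sorted runs) instead of fully sorted.

### Evaluation paths

Power is accumulated total-by-total.  Two paths share the same conditional
machinery:

- **Exact path** (default whenever feasible): for every total s, p-values
  of all splits carrying alternative mass are computed against the
  windowed conditional law (the window holds all but ~1e-14 of the null
  conditional mass plus every query split), and the alternative mass of
  the rejected splits is accumulated.  This equals a naive per-pair
  enumeration to ~1e-15 (tested).
- **Boundary-grid path** (high counts): exhaustive enumeration grows like
  the square of the pseudo-count scale and becomes infeasible around
  nμ ~ 10⁴–10⁵.  Above a workload cap (default 2.5e8 visited pairs) the
  conditional rejection boundary (lo(s), hi(s)) — a nondecreasing integer
  staircase — is computed *exactly* on a subsampled grid of totals (33–257
  points, budgeted at ~4e7 pairs) and interpolated monotonically in
  between; power then reduces to one pass over the control pseudo count
  with NB tail probabilities of the treatment side.  Interpolation can
  miscut a cell or two near staircase steps; at the scales where this path
  engages the observed error against the exact path is ~1e-4–1e-3 in
  power, and it vanishes as counts grow.  Average read counts of 2000 at
  n = 200 evaluate in a few seconds.  Totals beyond `max_total` (default
  5e6) raise a resource error rather than silently truncating.

## FDR control at design time

Rejecting every gene at marginal level α yields on average (m − m1)·α false
and m1·ε̄ true rejections, so the marginal level that equates the expected
FDR to the target f is

    α* = f · m1 · ε̄ / ((1 − f) · (m − m1)).

Defaults m = 10000, m1 = 100.  When *solving* for n at a user-chosen target
power, the plug-in form with ε̄ = target is used (α* fixed across the
search, so the printed sample sizes are reproducible from the header
alone).  When *evaluating* power at a fixed n, the achieved power is
unknown a priori, so a self-consistent fixed point of the same identity is
iterated (tolerance 1e-8, ≤ 50 iterations; a constant-power map reduces to
the plug-in value).  Because the exact test is discrete and conservative,
its realized size is slightly below α*, so realized FDR sits at or just
below f — the calibration simulation in the acceptance suite checks this.

## Sample-size search

Power is nondecreasing in n; the smallest n with power ≥ target is found
by exponential doubling followed by integer bisection, with monotonicity
spot-checked during the search (a violation beyond numerical jitter of
0.01 aborts with diagnostics rather than returning a wrong n).  Every
solve carries a bracketing certificate: the power at the returned n and at
n − 1.  A target unreachable within `n_max` (default 2000) raises an
error carrying the power at the cap.  Note that the published
representative solves sit on power boundaries: at (μ=30, φ=0.1) the power
at n = 10 is 0.7994 (confirmed by a 10⁷-draw Monte Carlo), so this
implementation certifies n = 11 where coarser legacy numerics printed 10.

Power curves split a total sample budget across allocation ratios, and
the power matrix evaluates a (per-group n) × (average read count) grid;
α* is held fixed across a curve or matrix (plug-in at the default 0.8
target, configurable) so cells are comparable.  In the operating range
where curves climb toward full power, the balanced 1:1 split dominates
the 2:1 and 3:1 splits row-wise (checked numerically in the acceptance
suite).  Interestingly, this is not universal: at very low power (small
totals, e.g. power below ~0.5 at μ=10, φ=0.5, ρ=2) the discrete exact
test can mildly favour a control-heavy 2:1 split, because extra control
samples sharpen the noisier low-count side of the comparison.

## Empirical mode

Real experiments spread μ_g over orders of magnitude with φ_g tied to
expression, and a single conservative (min count, max dispersion) pair
over-estimates n.  The empirical mode estimates the joint (μ_g, φ_g)
distribution from a reference count matrix:

1. **Normalization** — median-of-ratios against the gene-wise
   geometric-mean pseudo-reference (genes with any zero are excluded from
   the reference); factors are rescaled to geometric mean 1.  Normalized
   means are depth-invariant up to the inherent scale ambiguity
   (2^(1/n_samples) when one library doubles).
2. **Dispersion** — per-gene conditional maximum likelihood given the
   gene's total, evaluated on normalized (hence non-integer) counts as a
   pseudo-likelihood, profiled over log₁₀ φ ∈ [−8, 3]; then shrunk
   linearly (weight 0.5 by default) toward a trend φ(μ) = a/μ + b fitted
   across genes by nonnegative least squares.  This re-implements the
   tagwise-dispersion idea rather than matching any package bit-for-bit;
   parameter recovery on synthetic truth (median relative error < 5% for
   μ, < 25% for φ on a 2000 × 100 matrix) is the correctness standard.
3. **Filtering** — genes with normalized mean below `min_mean` (default 1)
   are dropped and counted in the provenance record, which (with the
   source-matrix hash) fully determines the distribution.

When per-sample group labels are supplied, estimation uses only the
control group (the model's μ_g is a control-group mean); otherwise the
whole matrix is treated as a control-like reference.  Gene-set restriction
(plain lists or GMT files; pathway support is offline by design) reuses
the same distribution.

Study-wide power resamples m1 genes uniformly without replacement
(with-replacement behind a flag), treating them as the differentially
expressed set under the assumption that DE genes share the all-gene
(μ, φ) distribution — an assumption inherited from the method and
surfaced here deliberately.  Each replication averages the sampled genes'
single-gene powers; 1000 replications by default are summarized by the
mean (median and quantiles available).  Per-gene powers are cached across
replications, and α* is computed once per call.  The empirical
sample-size search reuses the same seeded draws across candidate n, so the
objective is deterministic and inherits the core's monotonicity.

## Synthetic data generator

The generator stands in for a real reference matrix with known truth:
gene means log-normal (default log-mean ln 10, log-sd 1.2, spanning the
several-orders-of-magnitude range typical of bulk RNA-seq), dispersions
from the trend φ(μ) = 0.5/μ + 0.2 times log-normal gene noise (log-sd
0.2), per-sample library factors log-normal (log-sd 0.15), optional
treatment group with a chosen number of DE genes at a common fold change.
Counts are gamma-Poisson draws; everything is reproducible from the
scenario seed, and the truth table is emitted alongside.  It deliberately
omits batch structure, gene–gene correlation and outlier samples, so
passing tests demonstrate calibration and recovery *under the model*, not
robustness to real-data artefacts.

## Problem sizes used in the test suite

Simulation-backed checks run at sizes chosen to keep the full suite
comfortably reproducible on a single CPU: 10⁵ Monte-Carlo draws per grid
point for the power oracle, 20 replicate 2000-gene experiments for FDR
calibration (gene-mean log-sd 0.8 there so per-gene exact tests stay
cheap, and the sample-size recommendation solved with 5 seeded resampling
replications), 5000 resampling replications on a 200-gene distribution
for the estimator check, and a 2000 × 100 matrix for parameter recovery.

## Known limitations

- The boundary-grid path is an approximation between grid totals; its
  error is bounded empirically (~1e-3 worst observed) but not analytically.
- ω ≠ 1 relies on the common-mean convention μ̂ = s/(n0 + n1ω) and a
  variance heuristic for the conditional window; ω = 1 is exact.
- The dispersion estimator's pseudo-likelihood on normalized counts
  inherits a small bias when library sizes vary strongly.
- Design-time FDR control assumes the planned m1 and the anticipated power
  are roughly right; it is not a substitute for analysis-time adjustment
  on realized p-values.
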