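# Methods

## Problem and model

Given a genes × samples expression matrix, the goal is to find ordered
triplets (X1, X2 | X3) in which the correlation of X1 and X2 depends on the
expression level of the controller X3 — liquid association.  The package's
working model is a trivariate conditional normal model (CNM): conditional
on the controller value z,

    (X1, X2) | z  ~  BVN( mu_i(z) = m_i0 + m_i1 z,
                          sigma_i^2(z) = exp(v_i0 + v_i1 z),
                          rho(z) = tanh(c0 + c1 z) ).

Means are linear in z, log-variances linear in z, and the correlation is
linear in z on the Fisher-z scale, which keeps |rho| < 1 for every finite
z by construction.  The *full* model frees all ten parameters; the *simple*
model fixes m11 = m21 = v11 = v21 = 0 and keeps only correlation
dependence.  "No liquid association" is c1 = 0.  The modified liquid
association (MLA) of a fitted model is the average slope of the correlation
curve over the observed controller values,

    MLA = mean_z [ c1 (1 − tanh^2(c0 + c1 z)) ],

which is exactly 0 when c1 = 0 and approximately c1 for small c1.

Assumptions worth keeping in mind: conditional bivariate normality,
monotone (tanh-linear) correlation change in z, and Pearson correlation's
outlier sensitivity.  All three fail in practice for a minority of
triplets; the lack-of-fit cascade below exists for exactly those cases.

## Preprocessing

Genes with more than `max_missing_frac` (default 0.30) missing samples are
removed.  Each remaining gene is normal-quantile transformed —
non-missing values are replaced by Phi^-1(rank/(n+1)) with average ranks
for ties — and then standardized to exact sample moments (mean 0, variance
1, denominator n−1).  The n+1 plotting position avoids infinite quantiles
at the extremes; ties get average ranks.  The transform makes every gene
marginally normal, which both tames outliers and makes the magnitude
bounds below exact.  Missing values survive preprocessing (statistics are
computed on non-missing entries) and are resolved per controller.

## Stage 1: the rho_diff screen

For each controller, samples with a non-missing controller value are split
into equal-count tertiles by a stable sort on (value, original index);
when n mod 3 ≠ 0 the extra samples go to the low bin first, then the high
bin (n = 73 gives 25/24/24).  A controller with exactly two distinct
values is treated as binary: the two groups replace the outer tertiles and
rho_diff itself is the reported LA measure (no CNM stage).  A warning (not
an error) is raised when a bin has fewer than 15 samples, the point below
which correlation estimates get unstable.

The screening statistic is rho_diff = rho_high − rho_low, the pair's
Pearson correlation over the top tertile minus the bottom tertile.  Both
correlation matrices are computed as cross-products of per-bin
re-standardized submatrices (one pass per bin, never a per-pair loop).
Within a bin, a missing entry is mean-imputed (centered to zero) before
the cross-product; this is exact for complete data and a documented
approximation otherwise.  Genes with zero variance inside a bin get
undefined (NaN) entries, which are excluded from hits and counted in the
log rather than failing the controller.  An optional Spearman mode
rank-transforms each gene within the bin first, trading power for
robustness.  Triplets with |rho_diff| ≥ the threshold (default 0.5, i.e.
25% of the attainable range [−2, 2]) are emitted with the pair
canonicalized lexicographically (x1 < x2).

## Stage 2: estimation cascade

Each screened triplet is estimated as follows:

1. fit the full CNM; if it fits, report its MLA, Wald statistic and
   p-value (model code F);
2. on lack of fit, fit the simple CNM (code S);
3. on lack of fit again, use the robust direct estimate with bootstrap
   standard error (code R).

**Lack of fit** is declared when any of: the optimizer failed to converge;
some within-tertile empirical correlation deviates from the model-implied
tanh(c0 + c1 zbar_bin) by more than `lof_corr_tol` (default 0.35), which
catches non-monotone (e.g. U-shaped) correlation profiles; or a
Shapiro–Wilk test rejects normality of the model's standardized,
decorrelated residuals e1 and (e2 − rho e1)/sqrt(1 − rho²) at level
`lof_alpha` (default 0.01, split over the two series).  Calibration by
simulation: on data generated from the fitted model itself the check
passes ≥ 90–95% of the time at n = 1,000.

**Direct estimator.**  Samples are split into `n_bins` (default 3)
equal-count bins of x3.  Within each bin, x1 and x2 are re-centered and
re-scaled (population sd), so the within-bin mean of x1\*x2\* is exactly
the within-bin Pearson correlation, and x3 is discretized to its bin mean.
The estimate is

    MLA_hat = mean_s [ x1*_s x2*_s x3bar_b(s) ]  =  sum_b (n_b/n) rho_b x3bar_b,

a finite-difference version of the average correlation slope.  Three bins
minimize mean squared error for this estimator; the discretization of x3
(rather than using raw x3 in the product) is what ties the estimator to
the tertile correlations: on marginally normal data its maximum is the
mean absolute bin mean — sqrt(2/pi) ≈ 0.798 for a median split, ≈ 0.727
for tertiles — and makes its sign agree with rho_diff essentially always.
The bootstrap resamples sample indices with replacement (`n_boot` default
1,000, mandatory seed); resamples with a degenerate bin are redrawn and
counted.  p = 2 Phi(−|est|/SE).

**Optimization.**  BFGS on the analytic gradient of the exact bivariate
normal log-likelihood; the simple model is initialized from global
moments, the full model from per-variable linear regressions on z; both
get (c0, c1) from tertile correlations regressed on bin-mean z on the
Fisher-z scale.  Max 500 iterations; gradient tolerance 1e-8 per
observation.  Standard errors come from the inverse observed information
(numerical Hessian at the optimum, `statsmodels.tools.numdiff`); a
singular or indefinite Hessian marks the fit non-converged instead of
raising.

## Inference

p = 2 Phi(−√W) for Wald statistic W (equivalently the chi-square(1) tail).
Multiple testing uses Benjamini–Hochberg step-up with the *global* count
of fitted triplets as the test count, which can exceed the length of the
p-value vector at hand (a top list can be adjusted against the full
genome-scale count).  By default all fitted triplets (F/S/R) enter one
pool; `bh_pool="full_only"` restricts the adjustment to full-model tests,
adjusted against their own count, leaving other rows unadjusted (NaN).
Output rows are sorted by p-value, ties broken by |MLA| descending then
gene ids; two runs with the same config are identical, and a checkpointed
run resumed mid-way reproduces the uninterrupted result.  Per-triplet
bootstrap seeds are derived from the run seed and the triplet ids (CRC32),
so results do not depend on processing order or parallelism.

## Synthetic data and what the validation shows

Two generators drive validation.  `simulate_null` draws i.i.d. standard
normal entries (independent genes, identity covariance): under it every
triplet is null, so it probes false-positive behavior and the pure
sampling properties of the statistics.  `simulate_la_triplet` draws a
triplet from the CNM itself for power, parameter-recovery and calibration
studies.  Neither emulates real expression data's correlation structure,
heavy tails, batch effects or missingness patterns — passing tests show
the statistics behave as designed under the model, not that the model
describes any particular organism.

The concordance analysis enumerates *all* triplets of a small matrix
(feasible to a few hundred genes) and compares |rho_diff| with the direct
|MLA_hat|.  The default study conditions are G = 50 genes and N = 73
samples (the sample count of the motivating yeast cell-cycle design),
58,800 triplets per matrix.  On that null simulation the two statistics
correlate at ≈ 0.99 and the regression slope of |rho_diff| on |MLA_hat| is
≈ 2.75 — consistent with the ratio of the statistics' attainable maxima,
2/sqrt(2/pi) = 2.507 analytically and 2/0.727 ≈ 2.75 for the 3-bin
estimator.  The sensitivity curve reports, for each threshold, the
fraction of the exhaustive top-k |MLA_hat| triplets the screen would miss;
it is monotone by set nesting and essentially zero at the default 0.5
threshold on these conditions.  Simulated matrices are standardized but
not quantile-transformed before analysis (their margins are already
normal); real data goes through the full transform.

## Numerical and design choices

- Tertile remainder rule: extras to low, then high (any fixed rule works;
  this one is deterministic and keeps the middle bin smallest).  Boundary
  ties broken by original sample index via stable sort.
- rho_diff clipped to [−1, 1] per bin correlation before differencing;
  undefined bins propagate NaN rather than errors.
- The direct estimator discretizes x3 to bin means (see above); using raw
  x3 in the product inflates the estimator's independent noise and breaks
  its tight coupling to rho_diff.
- Wald p-values are floored at the smallest positive double to keep them
  in (0, 1] for downstream BH.
- Bootstrap n_boot = 1,000 by default; tests and examples use 100–200 for
  speed, which only affects the SE's own Monte-Carlo noise.
- The Shapiro–Wilk residual check subsamples to 5,000 points for large n.

## Limitations

- The Wald test is asymptotic; below ~15 samples per bin both stages are
  unstable (hence the warning).
- Mean-imputed within-bin missing handling biases correlations toward zero
  when missingness is heavy; the missingness filter (30%) bounds this.
- The screen can miss triplets whose correlation change concentrates in
  the middle tertile, since rho_diff only contrasts the outer bins; the
  sensitivity curve quantifies this loss for a given matrix and threshold.
- The lack-of-fit rule's tolerances (0.35 correlation deviation, 1%
  normality level) are package defaults, tunable via `RunConfig`; they are
  calibrated on simulation, not on any external dataset.
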