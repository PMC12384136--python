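# Methods

## Model and estimand

`iccperm` tests agreement between two raters who each score the same `n`
subjects on a continuous scale. The working model is the two-way
random-effects ANOVA with one observation per subject-rater cell,

    x_ij = mu + s_i + r_j + e_ij,        i = 1..n,  j = 1, 2,

with independent subject effects `s_i ~ (0, sigma_s^2)`, rater effects
`r_j ~ (0, sigma_r^2)` and residuals `e_ij ~ (0, sigma_e^2)`. Both
subjects and raters are treated as random draws from larger populations.
The estimand is the single-measure, absolute-agreement intraclass
correlation

    ICC(2,1) = sigma_s^2 / (sigma_s^2 + sigma_r^2 + sigma_e^2),

estimated from the mean squares of the two-way layout by

    rho_hat = (MSB - MSW) / (MSB + (k-1) MSW + (k/n)(MSR - MSW)),   k = 2.

Because "MSW" is used inconsistently in the reliability literature, the
package is explicit: MSW is the residual (interaction) mean square
`SSE/((n-1)(k-1))` of the two-way layout, not the one-way pooled
within-subject mean square. The two differ by the rater sum of squares;
the residual form is the one consistent with a model carrying a separate
rater term. The choice is isolated in `iccperm.icc.mean_squares` so it
can be swapped if a different convention is ever needed.

Negative `rho_hat` values are returned untruncated — clipping at zero
would bias the permutation null distribution. Note that unlike a product
-moment correlation, `rho_hat` is not bounded below by -1: when MSW
dominates both MSB and MSR the estimate can fall below -1. That is
handled explicitly wherever it matters (see Fisher's Z below).

## The four tests

All tests address `H0: ICC = 0` against the one-sided `H1: ICC > 0`.

- **F test.** `F = MSB/MSW` with degrees of freedom `(n-1, (n-1)(k-1))`,
  upper-tail p-value — the `rho0 = 0` special case of the classical
  absolute-agreement ICC F test. Exact under bivariate normality.
- **Fisher's Z.** `z = atanh(rho_hat) * sqrt(n-3)`, upper standard-normal
  tail. The variance constant `1/(n-3)` is the Pearson-style choice; it
  was selected over the intraclass variant `1/(n-3/2)` because only the
  former reproduces the test's documented small-sample conservativeness
  under bivariate normal nulls (empirical level about 0.035 at n = 10,
  rising to the nominal 0.05 by n = 50 — the package's own simulation
  reproduces this profile). Estimates below -1 yield `z = -inf`, p = 1:
  maximal evidence against the one-sided alternative.
- **Naive permutation.** Shuffle the second rater's column B times,
  recompute `rho_hat` (MSR included) on each permuted pairing, and report
  `p = (1/B) #{k : rho_k > rho_obs}` — strict inequality, divisor exactly
  B, no add-one smoothing. p can therefore be 0 and `p*B` is always an
  integer. This test is exact only under exchangeability of the pairing.
- **Studentized permutation (the headline method).** Same shuffles, but
  the statistic is `R = rho_hat / tau_n` with

      tau_n^2 = mu_22 / (mu_20 * mu_02),
      mu_pq = (1/n) sum_i (x_i1 - xbar_1)^p (x_i2 - xbar_2)^q,

  the large-sample variance surrogate borrowed from Pearson's
  correlation (divisor n, not n-1). Dividing by `tau_n` makes the
  permutation distribution asymptotically pivotal, which restores
  type-I-error control when the two raters' ratings are dependent but
  uncorrelated, heteroscedastic, or have unequal marginals — exactly the
  situations in which the other three tests drift to arbitrary levels.

The classical large-sample variance of `rho_hat`,
`2 rho^4 [(1/rho - 1)^2 + n k u^2]` with
`u = k(MSR-MSW)/(n(MSB-MSW))`, is exposed as a diagnostic
(`ICCEstimate.var_classical`) but never used for studentization: it is
unstable at `rho = 0`, the very point being tested. It is reported as
undefined when `MSB = MSW`.

Rejection is `p <= alpha` throughout, including for permutation p-values
computed with the strict `>` count; with B = 1000 a p-value of exactly
0.05 is attainable and counts as a rejection.

## Permutation implementation

With `rng = numpy.random.default_rng(seed)`, the B permutations are the
rows of `rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)`, applied to
the second column only. This contract is part of the API: a fixed seed
reproduces the p-value bit-for-bit, and the naive and studentized tests
share the same B shuffles so their contrast carries no extra permutation
noise.

The fast path exploits the fact that permuting one column leaves the
marginal sums, SST, the column means and hence MSR unchanged, so every
permuted `rho_hat` and `tau_n` is a function of just two inner products,
`sum cx*cy(pi)` and `sum cx^2*cy(pi)^2`. The observed statistic is
evaluated through the same vectorized kernel (an identity row prepended
to the permutation index matrix): a permutation that reproduces the
observed pairing then yields a bitwise-identical statistic, so the strict
comparison cannot be flipped by last-ulp differences between BLAS and
scalar summation orders. The test suite checks exact p-value equality
against a from-scratch loop implementation on dozens of small datasets.

A permuted sample with `tau = 0` (possible only for pathological
discrete data) is counted as non-exceeding — conservative — with a
logged warning.

## Simulation scenarios

The null scenario generators (module `iccperm.scenarios`) all have zero
population covariance between the columns, while most violate the
exchangeability the naive permutation test needs. Defaults are fixed at
the study conditions: replication 10,000, B = 1,000, alpha = 0.05,
sample sizes {10, 25, 50, 100, 200}.

| name     | process |
|----------|---------|
| mvn      | bivariate standard normal |
| exp      | `(X,Y) = r S^(1/2) u`, `S = diag(2,1)`, `r ~ Exp(1)`, `u` uniform on the unit circle |
| circular | uniform on the unit circle |
| t41      | `X = W+Z`, `Y = W-Z`, `W, Z` iid Student-t(4.1) |
| mvt      | bivariate t, 5 df, zero location, identity scale |
| mvnx     | 50:50 mixture of bivariate normals with correlations ±rho (exact Bernoulli component pick per row) |
| abnorm   | `X = |N(0,1)|`, `Y = Z·X` |
| binorm   | `X = Bern(0.1) + N(0, 0.05^2)`, `Y ~ N(0, sd = X+1)` |
| sqnorm   | `X ~ N(0,1)`, `Y = X^2 + N(0,1)` |
| unif     | `X = W+Z`, `Y = W-Z`, `W, Z` iid Unif(-1,1) |

Generator choices that were genuinely open, and how they were fixed:

- **exp.** The shape matrix `S = diag(2,1)` is applied as `S^(1/2)`
  (i.e. `X = sqrt(2)·r·cos(theta)`, `Y = r·sin(theta)`), so S is the
  covariance-scale of the elliptical law, not a per-axis sd. The
  alternative reading (`X = 2·r·cos(theta)`) was rejected by calibration:
  for radial laws the asymptotic level of the naive permutation test is
  fixed by the radius distribution alone (about 0.171 for an Exp(1)
  radius) while the F-test level also depends on the axis ratio, and only
  the `sqrt(2)` scaling reproduces the documented joint behaviour of all
  four tests under this scenario (F near 0.15, naive permutation near
  0.165 at large n, and the small-n profile). The per-axis-sd reading
  would put the F level near 0.12.
- **sqnorm.** "quadratic in X plus noise" is implemented as
  `Y = X^2 + eps`; any quadratic with no linear term preserves zero
  covariance since `E X^3 = 0`. Swappable.
- **binorm.** "sd of Y depends on X+1" is implemented as sd exactly
  `X+1` (positive with overwhelming probability given the 0.05 noise sd).
- **mvt.** Only the 5 df are specified; zero location and identity scale
  are assumed.
- **mvn4_5.** A scenario label that appears in published result tables
  with no stated generating process; the registry raises an explicit
  error rather than guess.

For power, `generate_power(rho, n)` draws a zero-mean, unit-variance
bivariate normal with correlation rho; with no rater effect and equal
marginals the population ICC(2,1) equals rho.

These generators emulate the *shape* pathologies of real rating data —
heavy tails, skew, dependence without correlation, variance coupling —
under iid sampling across subjects. They do not emulate rater drift over
time, bounded/discrete rating scales, missing cells, or subject-level
clustering; level control demonstrated here therefore speaks to
distributional robustness, not to violations of the iid-rows assumption
itself.

## Monte-Carlo engine

Each (scenario, n) cell derives a `SeedSequence` from the master seed and
a CRC-32 of the cell label, then spawns one child stream per replicate:
cells are independently reproducible and insensitive to which methods
are requested. All requested tests are applied to the same datasets
(shared shuffles for the two permutation tests), so method contrasts are
paired. Every rejection rate is reported with its Monte-Carlo standard
error `sqrt(r(1-r)/n_reps)`; comparisons in the test suite use 3·SE
bands, widening as `sqrt(1/n_reps)` in reduced-replication runs.

Problem sizes used by the checked-in analyses: the pytest suite runs
reduced-replication cells (typically 1,500-5,000 replicates with B = 500,
chosen so the whole suite completes in a few minutes), while
`scripts/acceptance.py` runs every reported cell at the full protocol of
10,000 replicates with B = 1,000.

## Numerical and degenerate-input conventions

- Ratings must be finite, n >= 3, exactly two raters.
- A fully constant matrix has no defined ICC (zero denominator): error.
- MSW = 0 (perfect agreement): the F test errors rather than fabricating
  p = 0; the permutation tests still run (`rho_hat = 1`, and `tau_n` is
  defined whenever both columns are non-constant).
- A constant rater column leaves `tau_n` undefined: the studentized test
  errors; the naive test does not need it.
- `run_all_tests` never throws for per-method degeneracies; it returns
  four entries with failures recorded in the `error` field.
- The ANOVA identity `SSB + SSR + SSE = SST` holds to 1e-10 relative
  tolerance (SSE is computed by subtraction with a clamp at zero against
  rounding).

## Known limitations

- Two raters only; the studentizer and the permutation scheme do not
  extend unchanged to k > 2.
- One-sided alternative only; no confidence intervals and no tests of
  non-zero nulls.
- The permutation test is asymptotically, not exactly, level-controlled
  under non-exchangeable nulls; at n = 10 its empirical level under the
  most hostile scenarios (variance-coupled ones like abnorm/binorm) runs
  a point or two above nominal, in line with its documented behaviour.
- Permutation p-values have resolution 1/B; with the strict-inequality
  convention the test is marginally anti-conservative at very small B
  (rejection probability `(floor(alpha*B)+1)/(B+1)` under exchangeable
  nulls), which is negligible at the default B = 1000.
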