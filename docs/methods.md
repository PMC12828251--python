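# Methods

## Model

For individual `l` in PSU `j` of stratum `i` observed at time `t` with
sampling weight `w_ijl(t)`, the mean trend is continuous piecewise-linear in
`t` with `k ≥ 0` joinpoints `τ₁ < … < τ_k` restricted to the observed time
grid and strictly interior to it:

- log-normal link (positive outcomes):
  `log y = β₀ + β₁ t + Σᵤ δᵤ (t − τᵤ)₊ + ε`, with the hinge strict
  (`(t − τ)₊ = 0` for `t ≤ τ`);
- logistic link (0/1 outcomes): the same linear predictor on the logit scale.

This *standard* (constrained) parameterization forces continuity at every
joinpoint. The *general* (unconstrained) parameterization gives each of the
`k+1` segments its own intercept and slope on half-open bins
`[τ_{s−1}, τ_s)` (the last bin closed on the right); records lying exactly on
a joinpoint are dropped from the unconstrained fit, since they belong to no
open segment interior. Both parameterizations share one code path for design
construction (`design.py`); segment slopes of the constrained model are
`β_{s,1} = β₁ + Σ_{u<s} δᵤ`.

## Estimation

Point estimates maximize the weighted pseudo-likelihood: weighted least
squares of `log y` (log-normal) and IRLS (logistic; relative step below
1e−10, at most 100 iterations, starting from the weighted-mean logit). Two
covariance matrices accompany each fit:

- **model-based Ĵ** — the inverse information with weights normalized to
  mean 1: `Ĵ = [SS_err/(n−p)] (X'WX)⁻¹` (log-normal),
  `Ĵ = (Σw/n) (X'WDX)⁻¹` with `D = diag(π̂(1−π̂))` (logistic). The
  normalization makes Ĵ invariant to rescaling all weights and makes
  `trace(Ĵ⁻¹V̂) ≈ p` under independent equal-weight sampling — the property
  the m.dAIC penalty presupposes.
- **design-based V̂** — the Taylor-linearization sandwich `B G B` with bread
  `B = (X'WX)⁻¹` or `(X'WDX)⁻¹` and meat `G` from between-PSU variation of
  estimating-equation score totals, `m/(m−1)`-corrected and centered within
  the stratum. Each time point's PSU sample is treated as an independent
  with-replacement draw: score totals are formed per **(PSU, year)** and
  centered within (stratum, year). A PSU reused for ten years therefore
  contributes ten units to V̂. This matches the per-time PSU indexing
  `j = 1..J_i(t)` of the design description, and it is the choice under
  which the selection criterion retains power against slope changes under
  clustering; summing scores across a PSU's in-sample years instead makes the
  average design effect absorb the persistent cluster-level level noise
  (which is irrelevant to trend shape) and the criterion loses essentially
  all power against slope changes. The cross-year dependence that PSU reuse
  induces is handled where it matters — in the aggregate module's cross-year
  covariance. Design degrees of freedom, by contrast, count each PSU once
  per sampling era (the union roster): PSUs minus strata.

A stratum-year cell with a single PSU is a hard error (no collapsing rules);
the generator never produces one, and silent collapse would distort V̂.

Fit statistics follow the survey-weighted definitions: `MSE = SS_err / Σw`;
the weighted R² takes its total sum of squares around the *stratum-by-year*
weighted means of `log y`, so R² ≤ ≈ 0 and ranks candidate joinpoint
locations identically to SS_err; `−2logL` is the weighted binomial deviance.

### Sufficient-statistic fitting

The segmented design depends on a record only through its time value, so all
of the above are exact functions of per-(PSU, year) totals: `Σw`, `Σw·z`,
`Σw·z²` (log-normal, with `z = log y` centered at its overall weighted mean
to avoid cancellation in the moment-based SS_err), `Σw·y` (logistic), and
record counts. `estimation.compress` builds these once per dataset; every
candidate fit in a grid search then costs `O(#PSU-years)` instead of
`O(records)`. Times are shifted to start at zero for conditioning and the
coefficients mapped back exactly afterwards.

## Joinpoint-number selection

For each `k` up to a cap (by default 0 for T ≤ 6 up to 5 for T ≥ 27,
following the usual T-based rule), a grid search fits the constrained model
at every feasible location tuple — at least 2 observed points strictly
outside the outer joinpoints and 2 strictly between neighbours, both
configurable — and keeps the best fit (max R² / min −2logL; ties go to the
lexicographically smallest tuple). `k` is then chosen to minimize

    m.dAIC = n·MSE + 2(2k+1)·δ̄            (log-normal)
    m.dAIC = (n/N)·(−2logL) + 2(2k+1)·δ̄   (logistic, N = Σ weights)

with ties preferring the smaller `k`. `2k+1` counts the non-intercept
unknowns (baseline slope, k slope changes, k locations). The average design
effect `δ̄` comes from one of two routes at the selected locations:

- **constrained**: `δ̄ = trace(Ĵ⁻¹V̂)` from the standard fit over the
  non-intercept coefficients `(β₁, δ₁…δ_k)`. Dropping the intercept mirrors
  the unconstrained route below and matches the penalty's parameter count;
  retaining it (available via `drop_intercept=False`) adds the intercept's
  design effect, which under long-lived cluster effects is an order of
  magnitude larger than the trend terms' and leaves the criterion unable to
  detect even large slope changes.
- **unconstrained**: fit the general model at the same locations, map its
  Ĵ and V̂ through the `(k+2)×(2k+2)` matrix `A_k` (first two rows select
  the first segment's intercept and slope; row `2+s` is the slope difference
  `β_{s+1,1} − β_{s,1}`), delete the intercept row/column, and take the
  trace over the remaining `k+1` coefficients. This route propagates the
  variability due to estimating the joinpoint locations into the penalty.

The constrained route is the recommended default for selection; the
unconstrained covariance is the recommended source of standard errors for
reporting (below).

## APC, AAPC and confidence intervals

Segment APC is `100(e^{β̂_{s,1}} − 1)`; on the logistic link the same
transform of the logit-scale slope is the annual percent change of the
*odds* (OAPC) — the weighted-odds derivation collapses to the identical
formula, so one code path serves both, labelled by link. Confidence
intervals use `β̂_{s,1} ± t_{d,0.975}·se` on the link scale with `d` the
design degrees of freedom, switching to a z-interval above d = 200. Point
estimates come from the constrained fit; `se` and the slope covariance come
from the unconstrained fit at the same joinpoints (the slope entries of its
V̂), which is the estimator that tracks location uncertainty. AAPC over an
interval is `100(exp(Σ γ̃_s β̂_{s,1}) − 1)` with `γ̃` the normalized overlap
lengths of each segment with the interval, and a z-interval from
`γ̃'V̂γ̃`; AAPC intervals always use z.

## Aggregate-level comparator

The yearly weighted mean (or proportion) `ŷ(t) = Σwy/Σw` is linearized
jointly across years: per-record influences `(w/W_t)(y − ŷ(t))` are summed
to PSU totals per year, centered within (stratum, year), and
`Cov(ŷ(t), ŷ(t'))` accumulates cross-products over PSUs present in both
years with factor `sqrt(m_t/(m_t−1))·sqrt(m_{t'}/(m_{t'}−1))` — years with
disjoint PSU sets get exactly zero covariance. The delta method maps Σ to
the log scale. Joinpoint models are fit to `log ŷ(t)` by GLS with weight
matrix `Σ⁻¹` (with-covariance) or `diag(Σ)⁻¹` (without); a singular Σ is an
error, never silently regularized. The number of joinpoints minimizes
`WBIC(k) = ln(WSSE_k/T) + (2k+2)·ln(T)/T`, the weighted-BIC convention with
`2k+2` parameters (intercept, slope, and k (δ, τ) pairs). Binary outcomes
are modeled as log-proportions. The series and Σ export to the
"estimates with covariance" CSV layout for cross-checks with desktop
joinpoint software.

## Synthetic finite population and sampling design

The generator emulates a national household survey's repeated cross-sections:

- a finite target population of `C` equal clusters of size `S` (defaults
  1000 × 1000) observed over 1997–2016, with one optional joinpoint at 2006
  (the series midpoint);
- continuous outcomes `log y = μ(t) + u_c + e`, `u_c ~ N(0, icc·σ²)`,
  `e ~ N(0, (1−icc)·σ²)`; defaults `μ(1997) = log 27`, `σ = 0.2`, baseline
  APC +0.5%/yr — resembling adult body-mass-index data. The cluster effect
  is drawn once per cluster and persists across all years, which is what
  correlates yearly estimates from reused PSUs;
- binary outcomes `y ~ Bernoulli(expit(η(t) + u_c))` with `u_c` variance
  solved from the latent-threshold relation `icc = σ_u²/(σ_u² + π²/3)`;
  defaults: baseline prevalence 0.20, baseline odds-APC +4%/yr — resembling
  adult obesity;
- per-segment slopes are `log(1 + APC/100)`, so an "APC difference" of −4.1
  means the post-joinpoint APC is 4.1 percentage points below the baseline;
  a difference of 0 encodes a true straight line (k = 0);
- sampling: the 20 years split into two blocks; within each block one SRS of
  80 clusters (8%) serves every year, and a fresh set is drawn for the next
  block (PSU identity is block-scoped). Individuals are drawn by SRS within
  each sampled cluster-year at 5/20/50% or a per-cluster-year U(0.05, 0.15)
  rate; weights are inverse inclusion probabilities and sum exactly to the
  population size in every year. One stratum; design df = 160 − 1 at full
  scale.

What the generator does **not** emulate: nonresponse and post-stratification
weight adjustments, unequal cluster sizes, individual-level covariates,
stratified first-stage sampling, and finite-population corrections from
joint PSU inclusion probabilities. Passing simulation checks therefore says
nothing about weight-adjustment artifacts or strongly informative designs;
it does exercise clustering, weighting, PSU reuse and the selection
criterion under realistic effect sizes.

The simulation harness generates each scenario's population once, resamples
it (default 100 replicates, seeds pre-drawn from the scenario seed so
results are order- and worker-independent), tallies the percentage of
replicates in which each method selects the true number of joinpoints
(exact-location agreement reported separately), and retains from each
replicate's best one-joinpoint model the estimates `(β̂₀, β̂₁, δ̂₁)` with
both diagonal variance estimates for the empirical-SD versus estimated-SE
comparison. Method failures are counted and reported, never dropped.

## Numerical choices and degenerate inputs

- Times are compared exactly for "record lies on a joinpoint" (the grid is
  copied from observed times); a 1e−9 relative tolerance guards noisy input.
- Normal-equation matrices with condition number above 1e12 raise a
  singular-fit error; candidate locations whose fit is singular are skipped
  in the grid search and reported only if all candidates fail.
- Logistic fits warn when `|x'θ̂| > 30` (separation); probabilities are
  clipped away from 0/1 in the deviance.
- Deterministic-within-cell data (zero total SS) yields R² = 1 for a perfect
  fit and NaN otherwise rather than dividing by zero.
- A summary interval must overlap the observed range; zero-overlap segments
  get γ = 0 and drop out of the AAPC.
- Reported m.dAIC and WBIC values are finite floats; ties break toward
  parsimony deterministically.

## Scale of the shipped evaluation

The acceptance script and the stochastic acceptance tests run the study at
its full population scale (1000×1000 clusters, n = 4000 per year at the 5%
rate) with 50–100 replicates per scenario. The reduced population that the
cluster-fraction-preserving `desk_scale()` helper provides is useful for
smoke tests but is *not* operating-characteristic-preserving: the fit-term
signal of a slope change scales with records per year while the design-effect
penalty scales only with the per-cluster take, so detection rates at reduced
scale are far below their full-scale values. Sufficient-statistic fitting
makes the full-scale runs affordable (a complete two-approach selection on
an 80 000-record replicate takes ~0.1 s).

## Known limitations

- The log-normal m.dAIC compares an absolute fit term (`n·MSE`, in squared
  log-outcome units) against a dimensionless penalty; its power against a
  given APC difference therefore depends on the absolute sample size per
  year, and very small slope changes (−0.41%) are below its detection
  threshold at the study's sample sizes under any noise level. The harness
  reports this honestly rather than rescaling the criterion.
- The unconstrained per-segment slope variances under per-year clustering
  overstate the replicate-to-replicate variability of the slope-change
  estimate when cluster effects persist across years (within-block contrasts
  benefit from noise cancellation the per-year sandwich cannot see); see the
  standard-error calibration test for the measured pattern.
- Only stratum/PSU Taylor linearization is implemented — no replicate
  weights (BRR/jackknife), no finite-population corrections.
- Joinpoint locations are restricted to observed time points; continuous-τ
  search is out of scope.
- Aggregate selection implements only the weighted-BIC route (no permutation
  test), and individual-level covariate adjustment is not supported.
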