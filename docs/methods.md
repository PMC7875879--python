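# Methods

## The model and the partitioning problem

`semscoretree` grows *structural equation model trees*: binary decision trees
whose nodes each hold the same template mean/covariance-structure model
fitted to a subsample.  A template maps a free-parameter vector θ (length q)
to an implied mean vector μ(θ) (length p, optional) and covariance matrix
Σ(θ) (p × p) through labelled pattern matrices in the factor-analytic form

    Σ(θ) = Λ Φ Λ′ + Θ,    μ(θ) = ν + Λ α,

where pattern entries are numeric constants (fixed) or string labels (free;
repeated labels impose equality).  Outcomes are assumed complete-case
multivariate normal.  Estimation minimizes the ML discrepancy

    F_ML = (ȳ − μ)′ Σ⁻¹ (ȳ − μ) + tr(S Σ⁻¹) − ln det(S Σ⁻¹) − p ,

where S is the maximum-likelihood (divide-by-n) sample covariance.  With
that convention n·F_ML and −2 log L differ by a θ-independent constant, so
the same estimates maximize the summed case-wise normal log density
−½{(y−μ)′Σ⁻¹(y−μ) + ln det Σ + p ln 2π} — the property the score tests rely
on.  Templates without a mean structure treat the mean as saturated: cases
are centered at the sample mean of the node, and mean parameters contribute
no scores.

Growth proceeds in four steps per node: fit the template; test every
covariate for parameter instability; pick the covariate with the smallest
p-value (Bonferroni-multiplied by the number of *available* covariates when
cross-covariate correction is on); if the adjusted p-value beats α, locate
the cut, split, and recurse.

## Score-based split evaluation

Case-wise scores (gradients of the case log-likelihood at θ̂) are sorted by
the covariate, decorrelated with the symmetric inverse square root of the
per-observation information, and cumulated into the process
CSP(s) = n^(−1/2) I^(−1/2) Σ_{h≤s} s_h, which converges column-wise to
independent Brownian bridges under homogeneity.  Functionals of the process
give the tests:

| statistic | covariate | functional | p-value |
|---|---|---|---|
| DM | continuous | max over s, k of \|CSP\| | analytic (Kolmogorov^q) |
| CvM | continuous | mean over s of Σ_k CSP² | simulated |
| maxLM | continuous | trimmed max of [s/n(1−s/n)]⁻¹ Σ_k CSP² | simulated |
| WDM | ordinal | weighted max of cumulative level bins | analytic (MVN rectangle) |
| maxLM_O | ordinal | weighted max of squared cumulative bins | simulated (exact finite-dim) |
| LM | categorical | Σ_l ‖B_l − B_{l−1}‖² over per-level sums | exact Gaussian quadratic form |

Design choices that were genuinely open:

* **Information estimator.**  Decorrelation uses the *expected* (model-
  implied) information by default.  Under the null every consistent choice
  is equivalent, but under a misspecified single-group fit the outer product
  of gradients absorbs the very heterogeneity the test is looking for and
  visibly deflates power; the model-implied information — what the
  established R implementations supply to the structural-change machinery —
  preserves it.  OPG and an observed-Hessian estimate remain available
  (`TreeOptions(information="opg")`, `information_estimate`).
* **Trim.**  maxLM and the maxLR candidate search omit 15 % of the sorted
  sample per tail (the classical recommendation for sup-LM statistics and
  the default of the reference structural-change software).  Configurable.
* **Categorical LM.**  The default statistic sums squared *consecutive
  differences* of per-level score sums (with B₀ = 0) and therefore depends
  on the level order; its p-value is computed from the exact null of that
  quadratic form (eigenvalues of the differenced multinomial-bridge
  covariance, Monte Carlo tail).  The order-invariant weighted variant
  Σ_l ‖B_l‖²/(n_l/n), which is χ² with q(m−1) degrees of freedom, is
  available as `variant="weighted"`.
* **Simulated nulls.**  CvM/maxLM nulls come from Brownian bridges on a
  1,000-point grid, 20,000 replicates, fixed internal seed, cached per
  (statistic, q, trim) in the process; binned statistics use exact
  finite-dimensional Gaussian draws at the level boundaries.  Simulated
  p-values are truncated to [1/(reps+1), 1] and carry a Monte Carlo SE.
  `semscoretree make-critical-values` exports the tables.
* **Ties and cut points.**  Partial maxLM statistics are evaluated only at
  boundaries between distinct covariate values, so a cut never separates
  tied cases; ties among equal partial statistics resolve to the earliest
  admissible boundary.  The located cut is the midpoint between adjacent
  distinct values (continuous) or the level boundary (ordinal); cases with
  covariate ≤ cut go left.

**Focus parameters** select columns of the *fully* decorrelated process
(decorrelation always uses the complete q × q information); the effective
dimension of the null is the number of focus columns.  **Global equality
constraints** estimate the named parameters once on the root sample and fix
them in every submodel; constrained parameters carry no scores and the
submodel's own information drives decorrelation.

## Likelihood-ratio split evaluation

For a fixed two-group split the statistic is the genuine likelihood ratio
LR = −2(log L_full − log L_sub) = Σ_j n_j {F[ȳ_j, S_j, θ̂_full] − F[ȳ_j,
S_j, θ̂_j]}, χ² with (J−1)q degrees of freedom.  Because the cut is
maximally selected, three corrections are provided: `naive` (Bonferroni over
cut points — demonstrably overcorrects for continuous covariates), `fair`
(seeded random split-half: one half selects the cut, the other tests it
unadjusted; the odd case joins the selection half), and `maxLR`, whose null
is the same trimmed sup-LM law as the score-based maxLM (the two statistics
are asymptotically equivalent) and is read from the same simulated tables —
or the exact finite-dimensional null when there are few candidate
boundaries, and the plain χ² tail when there is exactly one.  Group fits are
warm-started at the parent estimates; warm-started scans use a Fisher-
scoring fast path (expected-information Newton steps frozen at the start,
step-halving, fall-back to the transformed quasi-Newton optimizer whenever
scoring leaves the admissible region).  Cut localization by partitioned
log-likelihood is algebraically the max-LR boundary and is asserted as such
in the tests.

## Numerical choices

Variance parameters are optimized on the log scale so Σ(θ) stays positive
definite; estimates are reported on the natural scale.  Start values are
method-of-moments: the growth-curve template regresses occasion means on the
growth basis and solves an affine least-squares problem for the covariance
parameters; the factor templates use triad estimates for loadings.  On
non-convergence the start is perturbed deterministically (three restarts)
and the best point is returned flagged; the tree treats flagged group fits
as unavailable candidates, and a failed daughter fit rejects the split.
Templates with all loadings fixed expose their affine moment maps in closed
form, which makes the per-candidate group fits in LR scans cheap.  Fits are
refused below n = max(p + 1, 20) cases, leaves must keep at least 20 cases,
both configurable.

## The synthetic populations

* **Linear latent growth curve (4 occasions).**  Loading basis fixed at the
  occasion ages 6, 7, 9, 11; six free parameters.  Generating values:
  intercept mean 5.389, intercept variance 25.137, slope variance 2.808,
  intercept–slope covariance 0.745; group-2 overrides either a growth mean
  (5.695; which mean differs is a switch) or the three random-effect values
  (38.023, 4.247, 1.127).  The slope mean (2.0) and residual variance (10.0)
  are *reconstructions* — the original application does not print them — and
  are configurable; the null-calibration results do not depend on them.
* **Two-factor CFA (3 indicators each).**  Unit factor variances, all
  loadings 0.837 (70 % of indicator variance; residuals 1 − 0.837² ≈
  0.2994), no mean structure; 13 free parameters when fitted.  Group
  differences: latent covariance 0 vs 0.471, or the first indicator's
  loading 0.837 vs 0.640 with covariance 0.471 in both groups and residuals
  held at their base values (the loading is the only difference).

The informative covariate encodes group membership deterministically through
its quantile threshold — the n₁ lowest-ranked values form group 1 (central,
1/3- or 1/6-type cuts; mirrored for counterbalancing) — so the true cut is
exactly the stated population quantile.  Ordinal covariates have six equally
occupied levels with group boundaries on level boundaries; noise covariates
are independent of the groups.  What the generator does *not* emulate about
real data: non-normal outcomes, missing values, correlated covariates,
covariate measurement error, and smooth (non-threshold) parameter drift —
passing tests therefore certify the algorithmic machinery and its
calibration under the stated conditions, not robustness to those features.

## Monte Carlo harness and problem sizes

Rejection in the harness is the root-node split decision — exactly the
published counting rule (a tree with more than one node is a type-I error;
power counts trees that split the sample).  The harness therefore evaluates
the root through the same code path `fit()` uses without growing deeper,
and shares each replication's fit across focus/constraint scenarios (at the
root a constrained fit coincides with the restriction of the unconstrained
optimum; both facts are asserted against full tree growth and explicit
refits in the test suite).  Summaries carry binomial Monte Carlo standard
errors, and reported cut-point RMSE is recomputed from the stored
per-replication errors.

The packaged test suite and `scripts/acceptance.py` run the null-calibration
design at 2,000 replications and the CFA focus/constraint designs at 1,000
replications — sizes chosen so the whole suite completes on a single desktop
core in minutes while keeping three-sigma binomial bands of roughly ±1.5
and ±2–4 percentage points respectively.

## Known limitations

* Complete-case multivariate-normal ML only; no FIML, no categorical
  outcomes, no robust estimators.
* The lambda-difference CFA population as printed (Δλ = 0.197 on one
  indicator) carries less than half the two-group noncentrality of the
  phi-difference population; its published rejection rates are not
  attainable from those generating values, and the corresponding acceptance
  comparison documents the shortfall rather than adjusting the generator.
* sup-LM p-values for continuous covariates use simulated asymptotic tables;
  at very small node sizes (n ≲ 100) the bridge approximation is rough and
  the binned finite-dimensional null (few distinct values) or the fair/naive
  methods are preferable.
* Focus parameters under the naive/fair LR methods use a constrained
  two-group comparison with df = |focus|; this path is experimental and not
  validated against published rates (the score and maxLR paths are).
* One covariate is evaluated after another; node evaluations are
  deterministic given the tree seed (per-covariate RNG streams are derived
  by stable spawning), so results are reproducible but not parallelized.
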