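# Methods

## Problem setting

Longitudinal clinical microbiome cohorts produce clustered data: each
patient contributes a variable number of sputum samples across clinical
states, and measurements within a patient are correlated.  `medimix`
estimates how much of an exposure's effect on a continuous outcome
(FEV1%, percent-predicted lung function) is transmitted through the
microbiome, either through individual genera (taxa mode, high
dimensional) or through a community summary (alpha diversity; community
mode, single mediator).  The causal decomposition follows the standard
product-of-coefficients construction inside a pair of linked linear
mixed-effects models (an SEM in the two-regression sense).

Structural assumptions: linear relationships, mediators measured without
error, no outcome-to-mediator feedback, and no unmeasured confounding of
the exposure-mediator or mediator-outcome relationships.  Time is not
modeled explicitly: a patient-level random intercept absorbs stable
between-patient heterogeneity but not disease progression.

## Mediator transform

Counts are compositional; genus counts are transformed to pseudo-counted
log10 proportions per sample:

    Mlog[k, t] = log10((M[k, t] + 0.5) / D[k]),    D[k] = sum_t M[k, t].

The pseudo-count 0.5 is added to the numerator count and the depth is
left unmodified, which keeps the transform finite at zero counts and
makes `sum_t 10^Mlog[k, t] = 1 + 0.5 H / D[k]` an exact identity used as
a self-check in the tests.  The alternative placement (0.5 added to the
proportion) is available via `lognorm_transform(..., placement="proportion")`;
it compresses zeros toward log10(0.5) and is not the default.

## Outcome model (taxa mode)

Per cluster i (patient) with m_i samples:

    Y_i = beta_T T_i + sum_t beta_{M_t} Mlog_{i,t} + beta_C C_i
          + gamma_i Z_i + eps_i,

with gamma_i a scalar random intercept (Z_i a column of ones), eps_i
homoscedastic noise, and p = 2 + H + c fixed effects that can exceed the
total sample size N.  Fixed effects are estimated without estimating the
random-effect variance psi or the noise variance: a working covariance
proxy per cluster,

    Sigma_a^i = a Z_i Z_i' + I_{m_i},

whitens the data blockwise, (Xa, Ya) = (Sigma_a^{-1/2} X, Sigma_a^{-1/2} Y),
and a single scalar a tunes how much within-cluster correlation the
proxy absorbs.  The lasso objective is scaled by the effective sample
size Tr(Sigma_a^{-1}) = sum_i [(m_i - 1) + 1/(1 + a m_i)]:

    beta_hat = argmin 1/(2 Tr(Sigma_a^{-1})) ||Ya - Xa beta||^2
               + lambda ||beta||_1.

Coordinates used for inference are debiased with a nodewise-lasso
correction score w_j = Xa_j - Xa_{-j} kappa_j:

    beta_j^db = beta_j + w_j'(Ya - Xa beta_hat) / (w_j' Xa_j),

with the clusterwise variance estimate
V_j = sum_i [(w_j^i)' r_i]^2 / (w_j' Xa_j)^2 (r the lasso residual) and
SE_j = sqrt(V_j).  In the low-dimensional limit (lambda -> 0, p << N)
the debiased estimator collapses exactly onto generalized least squares
under Sigma_a; this is asserted in the test suite.

### Tuning

* `a`: chosen by 5-fold cluster-level cross-validation (clusters are
  never split across folds) over the candidate grid
  {0.05, 0.1, 0.25, 0.5, 1, 2, 4, 8}, scoring the raw-scale held-out
  error ||Y_held - X_held beta_hat||^2 minimized over lambda; ties go to
  the smaller a.  a = 0 (identity proxy) is allowed for testing.
* `lambda`: grid {2.0, 1.9, ..., 0.1} x sqrt(2 log(p) / N), same
  cluster folds; ties go to the larger (sparser) lambda.  For p < 2 the
  base rate falls back to sqrt(2/N) (logged).
* nodewise `lambda_j`: same multiplier grid and folds, selected per
  coordinate on the whitened scale.
* The intercept is included unpenalized (the outcome is far from
  zero-mean) and is profiled out of the lasso exactly: the quadratic is
  minimized over the intercept in closed form by projection, so this is
  not an approximation.  Columns are not standardized by default — the
  mediators share the log10-proportion scale and the exposure is binary
  — but `standardize=True` is available.

### Numerical choices

* Inverse square roots of the compound-symmetric proxy blocks use the
  closed-form eigenstructure (eigenvalue 1 + a m on the constant vector,
  1 elsewhere), which is exact and O(m) per cluster.
* Lasso solves use coordinate descent with a duality-gap convergence
  check; a gap above 1e-3 x ||y||^2 raises rather than returning an
  unconverged fit.
* A correction score with |w_j' Xa_j| <= 1e-10 ||Xa_j||^2 (exactly
  collinear columns) raises a "degenerate correction score" error.

## Mediator models and REML

Each mediator (and the community-mode outcome) is fitted with a
random-intercept linear mixed model by REML.  The solver profiles the
restricted likelihood down to the variance ratio theta = psi / sigma_e^2
using per-cluster sufficient statistics and the Sherman-Morrison
identity, evaluates a vectorized theta grid, and refines with bounded
1-D minimization (absolute log-theta tolerance 1e-10).  Two boundary
cases are handled explicitly:

* psi = 0: if the theta = 0 criterion is at least as good as the
  interior optimum, the boundary is reported and the fixed effects
  coincide with OLS (asserted to 1e-8 in tests).
* sigma_e^2 -> 0 (zero within-cluster residual variance): the profiled
  likelihood is unbounded and path-dependent, so when theta diverges the
  solver switches to the exact limit — ordinary regression on cluster
  means with psi_hat = RSS / (n - p) — which reproduces the balanced
  ANOVA closed form.

For balanced designs with an interior optimum the estimates agree with
the ANOVA closed form and with statsmodels' MixedLM (the independent
oracle in the tests) to ~1e-4.

## Effect composition

For contrast reference -> comparison (T = 1 for the comparison level):

    direct   = beta_T^db            (debiased, from the outcome model)
    indirect_t = delta_T^t x beta_{M_t}^db
    total    = direct + sum_t indirect_t.

The identity total - direct - sum(indirect) = 0 holds by construction
and is asserted to machine precision for every fit.  A mediator whose
REML fit fails yields a missing (NaN) indirect effect that is excluded
from the total with a prominent warning — never silently zeroed.
Clinical-state contrasts are fitted on the two-state subset (pairwise),
reproducing each comparison independently; patients reduced to a single
sample by the subset are retained (the random intercept absorbs them).
Age enters both models as a covariate by default.

## Bootstrap inference

Patients are resampled with replacement (cluster bootstrap, preserving
within-patient correlation); duplicated patients receive fresh cluster
ids.  Each resample re-runs the entire analysis including tuning
(default B = 3000, matching standard practice for BCa intervals at the
95% level).  Reported per effect:

* estimate: the mean of the resample estimates (the original-sample
  estimate is kept alongside);
* 95% BCa interval: bias correction z0 = Phi^{-1}(#{theta* < theta_hat}/B)
  (clipped to (1/(B+1), B/(B+1))), acceleration from the
  delete-one-cluster jackknife skewness (0 when fewer than 3 clusters),
  quantiles by linear interpolation.  An all-equal bootstrap
  distribution yields a degenerate (c, c) interval, logged;
* p-value: max(2 min(P[theta* <= 0], P[theta* > 0]), 1/B), capped at 1
  — the two-tailed proportion with a 1/B floor so finite resampling
  never produces p = 0;
* Benjamini-Hochberg adjustment across the H mediator indirect effects
  within each contrast (direct/total are single hypotheses and keep
  their raw p).

Per-resample RNG substreams derive from (seed, resample index), so
results are bit-identical for any worker count; resamples whose fit
fails are dropped with a recorded count, and more than 5% failures is a
hard error.

## Synthetic data generator

Study-scale defaults mimic the cohort the pipeline targets: n = 89
patients, 2-24 samples each, H = 47 genera, ages 6-54, an FEV1%-like
outcome (intercept 58, residual SD 8, patient-intercept variance 100),
and sequencing depths 2,000-20,000 reads.  Exposure is a binary clinical
state varying within patient (or a patient-level phenotype in
`between_cluster` mode).  Latent genus log10 abundances are
baseline + delta_T T + patient intercept + noise; counts are multinomial
draws from the softmax composition (an optional Dirichlet layer adds
overdispersion); the outcome is generated from the *true* log10
proportions so that the error introduced by the pseudo-count transform
is a measured property of the pipeline, not baked into the truth.

Effect-size defaults are chosen to match the scale of findings this
design can support: s = 5 active mediators with delta_T = 0.5 (a ~3x
fold change) and beta_M = 1.5, i.e. ~0.75 FEV1 units per active
mediator, against a direct effect of -5.  Active mediators are drawn as
*common* genera (baseline log10 abundance N(0.5, 0.5)): mediation
through a taxon whose counts are mostly zero is unidentifiable at finite
depth, and large latent shifts on abundant taxa leak through the softmax
normalizing constant into every genus's log proportion (composition is a
zero-sum game).  Both phenomena — count censoring of rare taxa and
compositional leakage — are real features of such data; the defaults
keep them present but moderate, so recovery tests measure the method
rather than the identifiability limit.  What passing tests on this
generator do *not* show: robustness to overdispersion beyond the
optional Dirichlet layer, taxonomic misassignment, batch effects, or
time trends within patients.

The community-mode generator produces a single Gaussian mediator with
(delta_T, beta_M, beta_T) = (1, -2, -3) by default (true indirect -2,
total -5) under the same clustered design.

## Test and acceptance problem sizes

Simulation scales in the test suite are the package's own choices:
debiased-lasso support recovery uses 50 replicates of n = 50 clusters
(sizes 4-10), p = 100, s = 5, unit variances; community recovery uses 50
replicates at study scale; bootstrap calibration uses 100 replicates of
n = 40 clusters (sizes 2-6) at B = 500 (null rejection) and B = 1000
(coverage); `scripts/acceptance.py` bootstraps a reduced taxa cohort
(n = 30, H = 20, B = 40) alongside a single full study-scale taxa fit.

## Known limitations

* The working-proxy approach deliberately avoids estimating psi and
  sigma_e^2 in the high-dimensional outcome model; no standard errors
  are produced for the lasso (non-debiased) coordinates.
* Random effects are intercept-only; no random slopes, crossed/nested
  designs, or serial correlation structures.
* Exposure contrasts are strictly pairwise (two levels per fit).
* The indirect-effect decomposition on compositional mediators is
  relative to the log-proportion scale; it does not identify absolute-
  abundance mediation.
* BCa intervals and the proportion p-value are different statistics;
  exact duality between "CI excludes 0" and "p < 0.05" is not guaranteed
  (the suite asserts approximate coherence only).
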