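# Methods

## The model

Two binary outcomes per child — stunting (height-for-age z score below
−2 SD) and anaemia (altitude-adjusted haemoglobin below 11 g/dl) — are
modelled jointly.  For child *i* in cluster *c* with indicator-coded
covariate row *x_i*:

    logit P(y_i1 = 1 | u_c) = x_i' θ1 + u_c1
    logit P(y_i2 = 1 | u_c) = x_i' θ2 + u_c2
    (u_c1, u_c2) ~ iid MVN(0, Σ)

Σ is an unstructured 2×2 covariance: σ11 and σ22 measure within-cluster
heterogeneity of each outcome; σ12 is the scientific target, the
cross-outcome association induced by shared cluster environments.  At
σ12 = 0 the likelihood factorizes exactly into two univariate
random-intercept GLMMs.  Both linear predictors use the logit link, the
natural choice when effects are to be reported as odds ratios.

The random effects are placed at the *cluster* (enumeration-area) level.
Cluster-level grouping makes σ11 and σ22 identifiable from within-cluster
outcome correlation; a child-level pairing of the two outcomes alone would
leave the variances only weakly identified (one binary observation per
random effect).

## Estimation

The marginal likelihood per cluster is a 2-D integral of a product of
Bernoulli likelihoods against the MVN density.  It is evaluated by
**adaptive Gauss–Hermite quadrature**: for each cluster the integrand's
posterior mode is found by damped Newton iterations (vectorized across
clusters), the tensor-product Gauss–Hermite grid is centred at the mode and
scaled by the Cholesky factor of the inverse curvature, and the weighted
log-sum-exp gives the cluster's log-likelihood contribution.  One node per
dimension recovers the Laplace approximation.  The default of **7 nodes per
dimension** was checked against 15 nodes on representative fitted cohorts
(|Δ log-lik| < 1e−4; variance-component estimates identical to 4 decimals)
and against a dense Simpson-grid integration oracle on small instances
(|Δ| < 1e−6 at 25 nodes).

Σ is parameterized by its log-Cholesky factor (log l11, l21, log l22), so
the optimizer (L-BFGS-B with numerical gradients) works unconstrained and
every iterate is positive definite.  Diagonal log-scale entries are bounded
in [−6, 3], which spans variances from ~6e−6 (effectively the boundary) to
~400.  Starting values: per-outcome plain-logistic fits for θ (damped
Newton, in-package) and 0.1·I for Σ.  Convergence: relative log-likelihood
change below 1e−9 and projected gradient below 1e−5.  Estimation is
maximum likelihood via the actual marginal likelihood, not a linearized
pseudo-likelihood; pseudo-likelihood methods are known to bias variance
components for binary data, so published variance-component values from
such fits are treated as transform/reporting checks rather than numerical
fit targets.

Standard errors come from the inverse observed information — a central
finite-difference Hessian at the optimum in the unconstrained space —
delta-transformed to the (θ, σ11, σ22, σ12) scale.  A singular Hessian
flags SEs as unavailable rather than failing the fit.

### Degenerate cases

Clusters with a single child (or a single observed outcome) still
contribute a full 2-D integral; the curvature matrix remains positive
definite because the MVN precision is added to the (possibly zero)
conditional curvature.  Children missing one outcome contribute only the
observed row.  An outcome observed for no child aborts with a message.
Rows are sorted on (cluster id, child id, outcome), so estimates are
invariant to input record order at machine precision.

## Hypothesis tests

- **σ12 = 0** (covariance): likelihood-ratio test against the sum of the
  two univariate GLMM log-likelihoods.  With both variances positive the
  null is interior (σ12 may be negative), so T ~ χ²(1).  A Wald version
  (σ̂12/SE)² is available.  LRT is the default because it does not depend
  on the Hessian's quality.
- **σkk = 0** (variance): the null sits on the boundary of the parameter
  space, so the LRT uses the 50:50 mixture null, p = ½·P(χ²₁ ≥ T) for
  T > 0 and p = 1 at T = 0.  The reduced model is the plain logistic fit.
- Negative LRT statistics beyond 1e−6 raise an error (they indicate an
  optimizer failure), tiny negatives are clamped to zero.

## Goodness of fit

Children are grouped by identical covariate pattern, per outcome.  For
pattern *i* with *n_i* children, observed category proportions *y_ij* are
compared with the model's **population-averaged** probabilities
π̂_ij = E_u[expit(x'θ̂ + u)] (40-node Gauss–Hermite over the fitted
random-effect distribution): χ² = Σ_i n_i Σ_j (y_ij − π̂_ij)²/π̂_ij.
Degrees of freedom = total patterns − fitted parameters; the ratio χ²/df
near 1 (default bound 1.2) reads as no residual overdispersion.

## The synthetic cohort generator

The generator draws from exactly the model above, so every downstream
stage can be validated against known truth without restricted survey
microdata.  What it emulates, with defaults:

- **Structure**: 400 clusters, cluster sizes Poisson(8) truncated at 1
  (~3,200 children, matching the scale of a national child-biomarker
  subsample); lognormal sampling weights with mean 1 (σ = 0.3).
- **Covariates**: drawn independently per variable from category marginals
  chosen to approximate the observed frequency tables of the motivating
  survey (e.g. 72% rural, 9% low birth weight, 17% recent fever).  Real
  DHS covariates are mutually correlated; independence is a deliberate
  simplification since no joint distribution is published.
- **Effects**: θ slopes default to the published multivariable point
  estimates for the seven reported covariates.  One published stunting row
  ("<20 months") prints an estimate whose sign contradicts its own odds
  ratio; the sign-corrected value (−0.829 = log 0.436) is used.
  Intercepts are not published; they are set once, analytically, as
  logit(target prevalence) − E[x'θ] under the covariate marginals, with
  targets 43% (stunting) and 51% (anaemia) — the headline prevalences.
  This ignores the small marginal attenuation from the random effects, so
  simulated prevalences land within a few points of the targets.
- **Covariance**: defaults σ11 = 0.104, σ22 = 0.314 as published.  The
  published covariance estimate (1.000) violates positive semidefiniteness
  against those variances (1.000² > 0.104·0.314); the default caps σ12 at
  the PSD boundary √(σ11σ22) ≈ 0.181 and the anomaly is documented here
  rather than silently reproduced.
- **Biomarker backfilling**: given binary outcomes, altitude ~ U(1400,
  3400) m, adjusted haemoglobin from truncated normals strictly below/above
  the 11 g/dl cutoff, HAZ likewise around −2 SD, then haemoglobin is
  un-adjusted using the drawn altitude so derive → classify reproduces the
  outcomes exactly (a 1e−6 margin keeps float round-trips off the cutoff).
  The truncated-normal locations (9.5/12.5 g/dl, −2.8/−0.7 SD) are
  realistic for this age group but carry no inferential weight.
- **Reproducibility**: a single seed is split via `SeedSequence.spawn`
  into four independent PCG64 streams (structure/covariates, cluster
  effects, outcome draws, weights); biomarker backfilling takes its own
  seed.  Identical seeds give identical cohorts byte-for-byte.

Because the generator *is* the fitted model, passing parameter-recovery
tests demonstrates correctness of the likelihood and optimizer, not
robustness to real-data features such as covariate dependence, informative
weights, spatial structure, or misspecified link functions.

## Outcome derivation conventions

- Altitude adjustment: the CDC polynomial used by the DHS program,
  adjustment = max(0, −0.032·A + 0.022·A²) g/dl with A = altitude in
  thousands of feet, subtracted from raw haemoglobin.  The convention is
  overridable; records without altitude use raw Hb and are logged.
- Severity bands half-open: severe < 7, moderate [7, 9), mild [9, 11);
  strict comparison at every edge (Hb exactly 11 is not anaemic; HAZ
  exactly −2 is not stunted).
- Children under 6 months are excluded from the anaemia outcome (left
  missing) when age is recorded, matching survey testing practice.
- An optional severe-stunting flag at HAZ < −3 SD exists, but the joint
  model consumes only the binary outcomes.

## Screening conventions

Pearson chi-square on weighted counts without a design-effect (Rao–Scott)
correction — the conventional spreadsheet-style crosstab workflow; a
warning notes that these p-values are not design-based.  Retention is
strict p < 0.2 for *either* outcome (union rule); ties at exactly 0.2 are
dropped.  p-values display as three decimals with "<0.001" below
resolution.

## Problem sizes used in the shipped studies

Chosen once as desk-scale study conditions: oracle checks on ≤3-cluster
instances; quadrature-convergence and factorization checks at 50–60
clusters; parameter recovery at 400 clusters × Poisson(8) over 5
replicates; type-I error of the covariance LRT at 150 clusters ×
Poisson(5), intercept-only, over 500 replicates (rejection band 0.03–0.08
around the nominal 0.05).

## Known limitations

- Two outcomes only; the architecture fixes K = 2.
- Unweighted maximum likelihood: sampling weights inform the descriptive
  cross-tabs but not the GLMM likelihood (design-based variance estimation
  is out of scope).
- ML variance components carry the usual small-sample downward bias
  (no REML analogue is implemented); visible as a few-percent shrinkage of
  σ̂12 at 400 clusters.
- No spatial or crossed random effects; no AIC-driven interaction search
  (AIC is reported per fit).
- The published grouped-data fit statistics from the restricted microdata
  are not reproduction targets; the package reports its own denominators
  and fit statistics.
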