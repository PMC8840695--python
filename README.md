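# jointglmm

Joint modelling of two correlated binary child-health outcomes — anaemia and
stunting — in cluster-sampled survey data, for epidemiologists and
biostatisticians analysing DHS-style child cohorts.

Anaemia (altitude-adjusted haemoglobin < 11 g/dl in children 6–59 months) and
stunting (height-for-age z score < −2 SD) are usually modelled separately,
which cannot quantify how strongly the two conditions travel together.  This
package fits them jointly: a bivariate logit generalized linear mixed model
with cluster-level random intercepts,

    logit P(y_i1 = 1 | u_c) = x_i' θ1 + u_c1        (stunting)
    logit P(y_i2 = 1 | u_c) = x_i' θ2 + u_c2        (anaemia)
    (u_c1, u_c2) ~ iid MVN(0, Σ),   Σ = [[σ11, σ12], [σ12, σ22]]

where the unstructured 2×2 covariance Σ links the outcomes: σ12 > 0 means
clusters with excess stunting also carry excess anaemia.  When σ12 = 0 the
model factorizes into two separate univariate GLMMs.  The marginal likelihood
is maximized directly with adaptive Gauss–Hermite quadrature (mode-centred,
curvature-scaled tensor product; Laplace = 1 node), with Σ parameterized by
its log-Cholesky factor so the estimate is positive definite by construction.

Around the core model the package provides:

- **outcome derivation** — CDC/DHS altitude adjustment of haemoglobin,
  anaemia severity bands (7 / 9 / 11 g/dl), strict −2 SD stunting cutoff;
- **univariate screening** — weighted cross-tabulations, Pearson chi-square
  tests, the p < 0.2 either-outcome retention rule, and the planning
  sample-size formula n = z²p(1−p)/d²;
- **inference** — interior χ²(1) LRT for σ12 = 0, boundary 50:50-mixture
  LRTs for the variances, Wald alternatives, grouped Pearson goodness-of-fit
  with an overdispersion ratio, and OR/CI tables (OR = exp(estimate),
  CI = exp(estimate ± 1.96·SE));
- **a synthetic cohort generator** — DHS-like clusters, sampling weights,
  configurable covariate marginals and ground-truth (θ1, θ2, Σ), plus
  biomarker backfilling so the whole pipeline runs end to end without any
  restricted survey microdata.

## Worked example

```python
from jointglmm import (AnalysisConfig, build_stacked_design, default_codebook,
                       default_truth, fit_joint_model, fit_independent_models,
                       simulate_cohort, test_covariance_zero)

codebook = default_codebook()
truth = default_truth(n_clusters=200, sigma11=0.6, sigma22=0.6, sigma12=0.45,
                      seed=6)
records = simulate_cohort(truth, codebook)
design = build_stacked_design(records, list(truth.variables), codebook)

cfg = AnalysisConfig(compute_se=False)
joint = fit_joint_model(design, cfg)
independent = fit_independent_models(design, cfg)
res = test_covariance_zero(joint, independent)
print(f"sigma12_hat = {joint.Sigma.sigma12:.3f}")
print(f"covariance LRT: T = {res.statistic:.3f}, p = {res.p_value:.4f}")
```

prints

```
sigma12_hat = 0.550
covariance LRT: T = 31.547, p = 0.0000
```

The estimated cross-outcome covariance (0.550) sits within sampling error of
the generating value (0.45 at 200 clusters), and the likelihood-ratio test
firmly rejects σ12 = 0: the two
outcomes are associated through their shared cluster environment.  The
`examples/` directory walks through each capability (simulation, outcome
derivation, screening, joint fitting, variance tests and goodness-of-fit,
full pipeline) as short narrative scripts.

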