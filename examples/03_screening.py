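"""Univariate screening: weighted cross-tabs, chi-square tests and the
p < 0.2 retention rule that decides which covariates enter the joint model.
"""

from jointglmm import (
    default_codebook,
    default_truth,
    required_sample_size,
    row_percentages,
    screen_covariates,
    simulate_cohort,
    weighted_crosstab,
)

codebook = default_codebook()
records = simulate_cohort(default_truth(n_clusters=400, seed=4))

table = weighted_crosstab(records, "wealth", "stunted")
print("weighted counts (wealth x stunting):")
print(table.round(1))
print("\nrow percentages:")
print(row_percentages(table).round(1))

screen = screen_covariates(records, codebook, alpha=0.2)
print("\nscreening table:")
print(screen.to_frame().to_string(index=False))
print("\nvariables entering the joint model (p < 0.2 for either outcome):")
print(screen.retained_union)

exact, ceiling = required_sample_size(p=0.51)
print(f"\nplanning sample size at prevalence 0.51: {exact:.2f} "
      f"(ceil {ceiling})")
# Variables simulated with nonzero slopes should be retained; 'sex' has no
# effect in the generator and is usually screened out.
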