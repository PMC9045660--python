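"""Fit the three random-intercept logistic biomarker models and print ORs.

Each marker (LGD histology, p53, SOX2) gets its own mixed-effects logistic
regression with fixed effects (time, standardized age, gender, BE length,
esophagitis) and a patient-level random intercept, fitted by adaptive
Gauss-Hermite maximum likelihood. Odds ratios above 1 mean a higher
probability of an aberrant call when the covariate is present/larger.
"""

from besurv import (
    apply_eligibility_filters,
    default_truth,
    fit_mixed_logistic,
    odds_ratios,
    simulate_cohort,
    standardize_age,
)

cohort, _ = simulate_cohort(default_truth(400), seed=7)
cohort, _ = apply_eligibility_filters(cohort)
cohort = standardize_age(cohort)

for marker in ("lgd", "p53", "sox2"):
    fit = fit_mixed_logistic(cohort, marker)
    print(f"\n=== {marker.upper()} (n_obs={fit.n_obs}, "
          f"sigma_b={fit.sigma_b:.2f}, converged={fit.converged}) ===")
    table = odds_ratios(fit)
    for cov, row in table.iterrows():
        print(f"  {cov:<13} OR {row['or']:.2f} "
              f"({row['ci_lower']:.2f}; {row['ci_upper']:.2f})")
# With the shipped generator, expect e.g. a time OR near 1.17 for p53 and a
# long-segment OR near 2.8 — the generating values, recovered from data.
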