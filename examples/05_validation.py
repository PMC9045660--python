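"""Landmark AUC validation: dynamic joint model vs static baseline Cox.

Scores every patient at risk at each landmark year with (a) the joint
model's 3-year dynamic risk from their truncated history and (b) the
static Cox linear predictor from baseline covariates only, then compares
window AUCs with Harrell bootstrap optimism correction (small B here).
"""

from besurv import (
    SamplerConfig,
    ValidationConfig,
    apply_eligibility_filters,
    bootstrap_optimism,
    default_truth,
    fit_static_cox,
    simulate_cohort,
    standardize_age,
    static_risk_scores,
)
from besurv.validation import joint_model_recipe

cohort, _ = simulate_cohort(default_truth(250), seed=71)
cohort, _ = apply_eligibility_filters(cohort)
cohort = standardize_age(cohort)

sampler = SamplerConfig(n_chains=1, n_iter=900, n_burn=400, seed=0,
                        n_intervals=3)
recipe = joint_model_recipe(sampler, n_outer=30, n_inner=50, horizon=3.0)
cox = fit_static_cox(cohort)
config = ValidationConfig(landmarks=(1.0, 2.0, 3.0), horizon=3.0,
                          n_bootstrap=3, seed=13)
result = bootstrap_optimism(cohort, recipe, config,
                            static_scores=static_risk_scores(cox, cohort))

print(result.table.round(3).to_string())
print(f"\nfailed refits: {result.n_failed_refits} of {result.n_bootstrap}")
# auc_corrected = auc_apparent - mean bootstrap optimism; a corrected
# dynamic AUC above auc_static at most landmarks is the headline pattern:
# longitudinal marker histories discriminate better than baseline status.
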