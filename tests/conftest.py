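import numpy as np
import pytest

from besurv.cohort import (
    Cohort,
    OutcomeRecord,
    PatientBaseline,
    VisitRecord,
    apply_eligibility_filters,
    standardize_age,
)
from besurv.jointmodel import SamplerConfig, fit_joint_model
from besurv.simulate import apply_ihc_sampling_design, default_truth, simulate_cohort


def make_patient(pid, age=60.0, female=0, event_time=5.0, event=0,
                 visit_times=(0.0, 1.0, 2.0), lgd=0.0, p53=0.0, sox2=0.0,
                 esophagitis=0, long_segment=1):
    """Hand-rolled single-patient pieces for contract tests."""
    baseline = PatientBaseline(pid, age, female)
    visits = [
        VisitRecord(pid, t, lgd, p53, sox2, esophagitis, long_segment)
        for t in visit_times
    ]
    outcome = OutcomeRecord(pid, event_time, event)
    return baseline, visits, outcome


def build_cohort(patients) -> Cohort:
    baselines, visits, outcomes = [], [], []
    for b, vs, o in patients:
        baselines.append(b)
        visits.extend(vs)
        outcomes.append(o)
    return Cohort(baselines, visits, outcomes)


@pytest.fixture(scope="session")
def sim_cohort():
    """Moderate simulated surveillance cohort with the study's
    outcome-dependent IHC sampling design, filtered and standardized."""
    truth = default_truth(150)
    cohort, gt = simulate_cohort(truth, seed=11)
    cohort = apply_ihc_sampling_design(cohort, "study", seed=12)
    cohort, _ = apply_eligibility_filters(cohort)
    return standardize_age(cohort), truth, gt


@pytest.fixture(scope="session")
def fitted_joint(sim_cohort):
    """Short-but-real MCMC fit shared across prediction/validation tests."""
    cohort, truth, _ = sim_cohort
    cfg = SamplerConfig(n_chains=2, n_iter=600, n_burn=250, seed=5,
                        n_intervals=3)
    return fit_joint_model(cohort, cfg), cohort, truth
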