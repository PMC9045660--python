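import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from besurv.cohort import (
    Cohort,
    OutcomeRecord,
    apply_eligibility_filters,
    standardize_age,
)
from besurv.validation import (
    ValidationConfig,
    bootstrap_optimism,
    fit_static_cox,
    static_risk_scores,
    window_auc,
)

from conftest import build_cohort, make_patient


def _outcomes(records):
    return [OutcomeRecord(f"P{i}", t, e, 0.5)
            for i, (t, e) in enumerate(records)]


class TestWindowAuc:
    def test_perfect_separation(self):
        outs = _outcomes([(1.5, 1), (2.0, 1), (9.0, 0), (9.0, 0)])
        risks = {"P0": 0.9, "P1": 0.8, "P2": 0.2, "P3": 0.1}
        assert window_auc(risks, outs, t=1.0, horizon=3.0) == 1.0

    def test_all_ties_give_half(self):
        outs = _outcomes([(1.5, 1), (2.0, 1), (9.0, 0), (9.0, 0)])
        risks = {p: 0.3 for p in ("P0", "P1", "P2", "P3")}
        assert window_auc(risks, outs, 1.0, 3.0) == 0.5

    def test_four_pair_enumeration_with_tie(self):
        outs = _outcomes([(1.5, 1), (2.0, 1), (9.0, 0), (9.0, 0)])
        risks = {"P0": 0.7, "P1": 0.4, "P2": 0.4, "P3": 0.2}
        # pairs: (.7>.4)=1, (.7>.2)=1, (.4==.4)=.5, (.4>.2)=1 -> 3.5/4
        assert window_auc(risks, outs, 1.0, 3.0) == pytest.approx(0.875)

    def test_undefined_when_no_cases(self):
        outs = _outcomes([(9.0, 0), (9.0, 0)])
        assert window_auc({"P0": 0.1, "P1": 0.2}, outs, 1.0, 3.0) is None

    def test_censored_in_window_excluded_by_default(self):
        outs = _outcomes([(1.5, 1), (2.0, 0), (9.0, 0)])  # P1 censored at 2
        auc = window_auc({"P0": 0.9, "P1": 0.5, "P2": 0.1}, outs, 1.0, 3.0)
        assert auc == 1.0  # one case, one control

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(10, 120))
            T = rng.uniform(0.6, 10.0, n)
            E = (rng.random(n) < 0.4).astype(int)
            risks = {f"P{i}": float(np.round(rng.random(), 2))
                     for i in range(n)}
            outs = _outcomes(list(zip(T, E)))
            got = window_auc(risks, outs, 1.0, 3.0)

            cases = [risks[o.patient_id] for o in outs
                     if o.event and 1.0 < o.event_time_years <= 4.0]
            controls = [risks[o.patient_id] for o in outs
                        if o.event_time_years > 4.0]
            if not cases or not controls:
                assert got is None
                continue
            s = sum(1.0 if a > b else 0.5 if a == b else 0.0
                    for a in cases for b in controls)
            assert got == pytest.approx(s / (len(cases) * len(controls)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        T = rng.uniform(0.6, 10.0, n)
        E = (rng.random(n) < 0.5).astype(int)
        r = rng.random(n)
        outs = _outcomes(list(zip(T, E)))
        base = window_auc({f"P{i}": r[i] for i in range(n)}, outs, 1.0, 3.0)
        trans = window_auc({f"P{i}": math.exp(3 * r[i]) for i in range(n)},
                           outs, 1.0, 3.0)
        assert (base is None and trans is None) or base == pytest.approx(trans)

    def test_ipcw_equals_exclude_without_window_censoring(self):
        outs = _outcomes([(1.5, 1), (2.5, 1), (9.0, 0), (8.0, 0), (7.0, 0)])
        risks = {f"P{i}": x for i, x in enumerate((0.9, 0.3, 0.4, 0.2, 0.1))}
        a = window_auc(risks, outs, 1.0, 3.0, policy="exclude")
        b = window_auc(risks, outs, 1.0, 3.0, policy="ipcw")
        assert b == pytest.approx(a)


def _toy_cohort(n=60, seed=0, event_frac=0.3):
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n):
        ev = int(rng.random() < event_frac)
        t = float(rng.uniform(1.2, 6.0)) if ev else float(rng.uniform(4.0, 11.0))
        patients.append(make_patient(
            f"P{i}", age=float(rng.uniform(45, 80)),
            female=int(rng.random() < 0.3), event_time=t, event=ev,
            visit_times=(0.0,), lgd=float(rng.integers(2)),
            p53=float(rng.integers(2)), sox2=0.0,
            long_segment=int(rng.random() < 0.7)))
    c = build_cohort(patients)
    c, _ = apply_eligibility_filters(c)
    return standardize_age(c)


def _fixed_rule_recipe(cohort, seed):
    """Scoring rule that ignores the training data entirely."""
    def scorer(target, t):
        return {
            b.patient_id: (b.age_years / 100.0
                           + 0.3 * target.visits_of(b.patient_id)[0].lgd)
            for b in target.baselines
            if target.outcome_of(b.patient_id).event_time_years > t
        }
    return scorer


class TestBootstrapOptimism:
    def test_zero_replicates_degenerate(self):
        cohort = _toy_cohort()
        cfg = ValidationConfig(landmarks=(1.0, 2.0), n_bootstrap=0, seed=1)
        res = bootstrap_optimism(cohort, _fixed_rule_recipe, cfg)
        assert (res.table["auc_corrected"] == res.table["auc_apparent"]).all()
        assert (res.table["optimism"] == 0.0).all()

    def test_fixed_rule_has_no_optimism(self):
        cohort = _toy_cohort(n=120, seed=3)
        cfg = ValidationConfig(landmarks=(1.0, 2.0, 3.0), n_bootstrap=60,
                               seed=2)
        res = bootstrap_optimism(cohort, _fixed_rule_recipe, cfg)
        assert np.nanmax(np.abs(res.table["optimism"].astype(float))) < 0.05
        # identity corrected = apparent - optimism holds exactly
        t = res.table
        assert np.allclose(t["auc_corrected"], t["auc_apparent"] - t["optimism"])

    def test_fixed_seed_reproducible(self):
        cohort = _toy_cohort()
        cfg = ValidationConfig(landmarks=(1.0, 2.0), n_bootstrap=8, seed=11)
        r1 = bootstrap_optimism(cohort, _fixed_rule_recipe, cfg)
        r2 = bootstrap_optimism(cohort, _fixed_rule_recipe, cfg)
        assert r1.per_replicate == r2.per_replicate
        assert r1.table.equals(r2.table)

    def test_failing_refits_are_counted(self):
        cohort = _toy_cohort()
        calls = {"n": 0}

        def flaky_recipe(c, seed):
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise RuntimeError("no convergence")
            return _fixed_rule_recipe(c, seed)

        cfg = ValidationConfig(landmarks=(1.0,), n_bootstrap=6, seed=4)
        res = bootstrap_optimism(cohort, flaky_recipe, cfg)
        assert res.n_failed_refits == 3
        assert len(res.per_replicate) == 3


class TestStaticCox:
    def test_three_subject_partial_likelihood_closed_form(self):
        """Events at t=2 (x=1) and t=3 (x=0) with a censored x=1 subject:
        the score equation solves to beta = -log(2)/2."""
        patients = [
            make_patient("A", age=60, event_time=2.0, event=1,
                         visit_times=(0.0,), lgd=1.0),
            make_patient("B", age=60, event_time=3.0, event=1,
                         visit_times=(0.0,), lgd=0.0),
            make_patient("C", age=60, event_time=4.0, event=0,
                         visit_times=(0.0,), lgd=1.0),
        ]
        c = build_cohort(patients)
        c, _ = apply_eligibility_filters(c)
        c.age_scaler = (60.0, 10.0)
        fit = fit_static_cox(c, covariates=("lgd0",))
        assert fit.coefs[0] == pytest.approx(-math.log(2) / 2, abs=1e-5)
        assert fit.ties == "efron"

    @staticmethod
    def _marker_cox_cohort(n, log_hr, seed):
        rng = np.random.default_rng(seed)
        patients = []
        for i in range(n):
            x = int(rng.random() < 0.5)
            lam = 0.08 * math.exp(log_hr * x)
            t = float(rng.exponential(1 / lam))
            ev, t = (1, t) if t < 12.0 else (0, 12.0)
            t = max(t, 0.6)
            patients.append(make_patient(
                f"P{i}", age=float(rng.uniform(45, 80)), event_time=t,
                event=ev, visit_times=(0.0,), lgd=float(x)))
        c = build_cohort(patients)
        c, _ = apply_eligibility_filters(c)
        return standardize_age(c)

    def test_null_covariate_near_zero(self):
        c = self._marker_cox_cohort(400, log_hr=0.0, seed=6)
        fit = fit_static_cox(c, covariates=("lgd0", "age_std"))
        i = fit.names.index("lgd0")
        assert abs(fit.coefs[i]) <= 3 * fit.se[i]

    def test_recovers_known_log_hazard_ratio(self):
        c = self._marker_cox_cohort(1000, log_hr=math.log(2), seed=7)
        fit = fit_static_cox(c, covariates=("lgd0", "age_std"))
        i = fit.names.index("lgd0")
        assert abs(fit.coefs[i] - math.log(2)) <= 3 * fit.se[i]
        hr = fit.hazard_ratios()
        assert hr.loc["lgd0", "ci_lower"] < hr.loc["lgd0", "hr"] \
            < hr.loc["lgd0", "ci_upper"]

    def test_missing_baseline_markers_counted_as_normal(self):
        nan = float("nan")
        patients = [
            make_patient("A", age=55, event_time=3.0, event=1, p53=nan),
            make_patient("B", age=60, event_time=6.0, p53=1.0),
            make_patient("C", age=70, event_time=8.0, p53=nan, lgd=1.0),
        ]
        c = build_cohort(patients)
        c, _ = apply_eligibility_filters(c)
        c = standardize_age(c)
        fit = fit_static_cox(c, covariates=("age_std",))
        assert fit.n_missing_baseline_markers == 2
        scores = static_risk_scores(fit, c)
        assert set(scores) == {"A", "B", "C"}


class TestJointModelNestsCox:
    def test_alpha_zero_posterior_matches_cox_coefficient(self):
        """With both associations switched off, the joint model's
        esophagitis coefficient should concentrate near the static Cox
        estimate on a cohort simulated without marker-hazard coupling."""
        from besurv.jointmodel import SamplerConfig, fit_joint_model
        from besurv.simulate import default_truth, simulate_cohort

        truth = default_truth(350)
        truth.survival.alpha_value[:] = 0.0
        truth.survival.alpha_cumulative[:] = 0.0
        truth.survival.gamma[:] = [0.0, 0.0, 0.0, math.log(3.0)]
        truth.survival.baseline.log_rates[:] = math.log(0.01)
        truth.p_esophagitis = 0.3
        cohort, _ = simulate_cohort(truth, seed=19)
        cohort, _ = apply_eligibility_filters(cohort)
        cohort = standardize_age(cohort)

        cox = fit_static_cox(cohort,
                             covariates=("esophagitis", "long_segment",
                                         "age_std", "female"))
        i = cox.names.index("esophagitis")

        cfg = SamplerConfig(n_chains=1, n_iter=900, n_burn=350, seed=23,
                            n_intervals=2, estimate_value=False,
                            estimate_cumulative=False,
                            init_from_separate_fits=False)
        draws = fit_joint_model(cohort, cfg)
        post = draws.stacked("gamma[esophagitis]")
        assert np.all(draws.stacked("alpha_value[p53]") == 0.0)
        # agreement within combined asymptotic + Monte-Carlo tolerance
        tol = 2.0 * cox.se[i] + 2.0 * post.std() / math.sqrt(
            max(draws.ess["gamma[esophagitis]"], 4.0))
        assert abs(post.mean() - cox.coefs[i]) <= tol
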