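import math
from dataclasses import replace

import numpy as np
import pytest

from besurv.cohort import (
    Cohort,
    apply_eligibility_filters,
    standardize_age,
)
from besurv.hazard import (
    BaselineHazard,
    SurvivalParams,
    cumulative_hazard,
    expit_time_integral,
    hazard_at,
)
from besurv.jointmodel import (
    SamplerConfig,
    fit_joint_model,
    hazard_ratio_per_10pct,
    illustrative_risk_contribution,
    joint_log_likelihood,
)
from besurv.longitudinal import LongitudinalParams
from besurv.simulate import default_truth, simulate_cohort

from conftest import build_cohort, make_patient


def _params(rate=0.1, horizon=30.0, gamma=None, av=None, ac=None):
    return SurvivalParams(
        baseline=BaselineHazard(np.array([0.0, horizon]),
                                np.array([math.log(rate)])),
        gamma=np.zeros(4) if gamma is None else np.asarray(gamma, float),
        alpha_value=np.zeros(3) if av is None else np.asarray(av, float),
        alpha_cumulative=np.zeros(3) if ac is None else np.asarray(ac, float),
    )


def _funcs(pi_vals=(0.0, 0.0, 0.0), slope=0.0):
    pis = [lambda t, p=p: p + 0.0 * np.asarray(t) for p in pi_vals]
    ints = [lambda t, p=p: p * np.asarray(t, float) for p in pi_vals]
    return pis, ints


class TestHazard:
    def test_reduces_to_baseline(self):
        pis, ints = _funcs()
        h = hazard_at(2.0, _params(rate=0.07), pis, ints, np.zeros(4))
        assert h == pytest.approx(0.07)

    def test_value_association_saturated_marker(self):
        a = 1.3
        pis, ints = _funcs(pi_vals=(1.0, 0.0, 0.0))
        params = _params(rate=0.05, av=[a, 0, 0])
        h = hazard_at(4.0, params, pis, [lambda t: 0 * np.asarray(t)] * 3,
                      np.zeros(4))
        assert h == pytest.approx(0.05 * math.exp(a))

    def test_accumulated_association_constant_probability(self):
        c, p, lam, t = 0.8, 0.4, 0.03, 5.0
        pis, ints = _funcs(pi_vals=(p, 0, 0))
        params = _params(rate=lam, ac=[c, 0, 0])
        h = hazard_at(t, params, [lambda s: 0 * np.asarray(s)] * 3, ints,
                      np.zeros(4))
        assert h == pytest.approx(lam * math.exp(c * p * t))

    def test_outside_support_raises(self):
        pis, ints = _funcs()
        with pytest.raises(ValueError, match="support"):
            hazard_at(31.0, _params(horizon=30.0), pis, ints, np.zeros(4))


class TestCumulativeHazard:
    def test_constant_hazard_exact(self):
        pis, ints = _funcs()
        H = cumulative_hazard(0.5, 3.5, _params(rate=0.2), pis, ints,
                              lambda t: np.zeros(4))
        assert H == pytest.approx(0.6, abs=1e-10)

    def test_exponential_growth_closed_form(self):
        c, p, lam = 0.9, 0.5, 0.04
        params = _params(rate=lam, ac=[c, 0, 0])
        pis = [lambda t: 0 * np.asarray(t)] * 3
        ints = [lambda t: p * np.asarray(t, float)] + \
               [lambda t: 0 * np.asarray(t)] * 2
        t0, t1 = 0.5, 6.0
        H = cumulative_hazard(t0, t1, params, pis, ints, lambda t: np.zeros(4))
        closed = lam * (math.exp(c * p * t1) - math.exp(c * p * t0)) / (c * p)
        assert H == pytest.approx(closed, rel=1e-8)

    def test_smooth_pi_matches_dense_trapezoid(self):
        from scipy.special import expit

        params = _params(rate=0.05, av=[1.1, -0.4, 0.6], ac=[0.2, 0.1, 0.0],
                         gamma=[0.3, -0.2, 0.1, 0.4])
        pi_fns = [
            lambda t: expit(-1 + 0.3 * np.asarray(t, float)),
            lambda t: expit(0.5 - 0.2 * np.asarray(t, float)),
            lambda t: expit(-2 + 0.1 * np.asarray(t, float)),
        ]
        int_fns = [
            lambda t: expit_time_integral(-1.0, 0.3, 0.0, t),
            lambda t: expit_time_integral(0.5, -0.2, 0.0, t),
            lambda t: expit_time_integral(-2.0, 0.1, 0.0, t),
        ]
        w = np.array([0.4, 1.0, 1.0, 0.0])
        t0, t1 = 0.5, 7.5
        H = cumulative_hazard(t0, t1, params, pi_fns, int_fns, lambda t: w)
        ts = np.linspace(t0, t1, 100_001)
        hs = [hazard_at(t, params, pi_fns, int_fns, w) for t in ts[:: 1000]]
        # dense trapezoid over all 1e5 points, vectorized
        log_h = (math.log(0.05) + w @ params.gamma
                 + sum(params.alpha_value[k] * pi_fns[k](ts)
                       + params.alpha_cumulative[k] * int_fns[k](ts)
                       for k in range(3)))
        oracle = np.trapezoid(np.exp(log_h), ts)
        assert H == pytest.approx(oracle, rel=1e-6)

    def test_nondecreasing_in_endpoint(self):
        pis, ints = _funcs(pi_vals=(0.3, 0.2, 0.1))
        params = _params(rate=0.1, av=[0.5, 0.5, 0.5])
        Hs = [cumulative_hazard(0.5, t1, params, pis, ints,
                                lambda t: np.zeros(4))
              for t1 in (1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(Hs) > 0)


def _unit_long_params(beta_p53=None):
    beta = {m: np.zeros(6) for m in ("lgd", "p53", "sox2")}
    if beta_p53 is not None:
        beta["p53"] = np.asarray(beta_p53, float)
    return LongitudinalParams(beta=beta, D=np.eye(3))


class TestJointLogLikelihood:
    def test_empty_cohort_is_zero(self):
        c = Cohort([], [], [], age_scaler=(60.0, 10.0))
        assert joint_log_likelihood(c, _unit_long_params(), _params(),
                                    np.zeros((0, 3))) == 0.0

    def test_single_patient_hand_computation(self):
        """Censored patient, one visit, one observed marker, constant
        hazard h and no covariate/association effects:
        ll = log p_obs - h * (T - 0.5)."""
        nan = float("nan")
        patient = make_patient("A", age=60.0, event_time=4.0, event=0,
                               visit_times=(0.0,), lgd=nan, p53=1.0, sox2=nan,
                               esophagitis=0, long_segment=0)
        cohort = build_cohort([patient, make_patient("B", age=50.0)])
        cohort, _ = apply_eligibility_filters(cohort)
        cohort = standardize_age(cohort)
        cohort = cohort.subset(["A"])

        beta_p53 = np.array([0.7, 0, 0, 0, 0, 0])
        h = 0.11
        ll = joint_log_likelihood(
            cohort, _unit_long_params(beta_p53), _params(rate=h),
            np.zeros((1, 3)),
        )
        from scipy.special import expit

        expected = math.log(expit(0.7)) - h * (4.0 - 0.5)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_all_missing_visit_leaves_likelihood_unchanged(self):
        nan = float("nan")
        base = make_patient("A", event_time=6.0, event=1,
                            visit_times=(0.0, 1.0), p53=1.0)
        extra = make_patient("A", event_time=6.0, event=1,
                            visit_times=(0.0, 1.0), p53=1.0)
        extra[1].append(type(extra[1][0])("A", 3.0, nan, nan, nan, 0, 1))
        other = make_patient("B", age=47.0)

        def ll_of(patient):
            c = build_cohort([patient, other])
            c, _ = apply_eligibility_filters(c)
            c = standardize_age(c)
            truth = default_truth(2)
            return joint_log_likelihood(
                c, truth.longitudinal,
                replace(truth.survival, alpha_value=np.zeros(3),
                        alpha_cumulative=np.zeros(3)),
                np.zeros((2, 3)))

        assert ll_of(extra) == pytest.approx(ll_of(base), abs=1e-10)

    def test_invariant_to_patient_and_visit_order(self):
        truth = default_truth(30)
        cohort, gt = simulate_cohort(truth, seed=14)
        cohort, _ = apply_eligibility_filters(cohort)
        cohort = standardize_age(cohort)
        b = gt.b[[int(p[1:]) for p in cohort.patient_ids]]
        ll1 = joint_log_likelihood(cohort, truth.longitudinal, truth.survival, b)

        perm = np.random.default_rng(0).permutation(cohort.n_patients)
        shuffled = Cohort(
            baselines=[cohort.baselines[i] for i in perm],
            visits=list(reversed(cohort.visits)),
            outcomes=[cohort.outcomes[i] for i in perm],
            age_scaler=cohort.age_scaler,
        )
        from besurv.cohort import _validate
        shuffled = _validate(shuffled)
        ll2 = joint_log_likelihood(shuffled, truth.longitudinal,
                                   truth.survival, b[perm])
        assert ll2 == pytest.approx(ll1, rel=1e-12)


class TestHazardRatioScale:
    def test_per_10pct_transform(self):
        assert hazard_ratio_per_10pct(10 * math.log(1.26)) == pytest.approx(1.26)
        assert hazard_ratio_per_10pct(10 * math.log(1.43)) == pytest.approx(1.43)
        assert hazard_ratio_per_10pct(0.0) == 1.0

    def test_illustrative_contribution(self):
        assert round(illustrative_risk_contribution(0.2, 1.26), 2) == 0.25
        assert illustrative_risk_contribution(0.0, 5.0) == 0.0
        assert illustrative_risk_contribution(1.0, 1.26) == pytest.approx(1.26)
        with pytest.raises(ValueError):
            illustrative_risk_contribution(1.4, 1.0)


class TestSampler:
    def test_same_seed_identical_draws(self):
        truth = default_truth(40)
        cohort, _ = simulate_cohort(truth, seed=3)
        cohort, _ = apply_eligibility_filters(cohort)
        cohort = standardize_age(cohort)
        cfg = SamplerConfig(n_chains=1, n_iter=120, n_burn=60, seed=77,
                            n_intervals=2, init_from_separate_fits=False)
        d1 = fit_joint_model(cohort, cfg)
        d2 = fit_joint_model(cohort, cfg)
        for name in d1.params:
            assert np.array_equal(d1.params[name], d2.params[name])
        assert np.array_equal(d1.b_draws, d2.b_draws)

    def test_prior_only_run_recovers_prior_moments(self):
        truth = default_truth(25)
        cohort, _ = simulate_cohort(truth, seed=3)
        cohort, _ = apply_eligibility_filters(cohort)
        cohort = standardize_age(cohort)
        cfg = SamplerConfig(n_chains=2, n_iter=2500, n_burn=500, seed=1,
                            n_intervals=2, prior_only=True,
                            init_from_separate_fits=False)
        draws = fit_joint_model(cohort, cfg)
        for name in ("beta[p53,time]", "gamma[age_std]", "alpha_value[sox2]"):
            x = draws.stacked(name)
            ess = max(draws.ess[name], 10.0)
            mcse_mean = 10.0 / math.sqrt(ess)
            assert abs(x.mean()) <= 3 * mcse_mean
            # sd of N(0,10) prior; sd of the sd estimate ~ sd/sqrt(2 ess)
            assert abs(x.std(ddof=1) - 10.0) <= 3 * 10.0 / math.sqrt(2 * ess)

    def test_posterior_predictive_event_load_brackets_truth(
            self, fitted_joint, sim_cohort):
        """The expected-event-count functional sum_i 1 - exp(-H_i) over the
        observed at-risk windows, evaluated per posterior (theta, b) draw,
        must bracket its value under the generating truth parameters and
        the true random intercepts."""
        from besurv._likelihood import JointData
        from besurv.hazard import BaselineHazard

        draws, cohort, truth = fitted_joint
        _, _, gt = sim_cohort
        K = len(draws.knots) - 1
        data = JointData.from_cohort(
            cohort, BaselineHazard(draws.knots, np.zeros(K)))

        def event_load(data, long_params, surv, b):
            beta = long_params.beta_matrix()
            mn = [data.marker_process(k, beta[k], b[:, k]) for k in range(3)]
            s = data.node_w4 @ surv.gamma + surv.baseline.log_rates[data.node_seg]
            for k in range(3):
                v, I, _, _ = mn[k]
                s = s + surv.alpha_value[k] * v + surv.alpha_cumulative[k] * I
            H = np.bincount(data.node_pat, weights=data.node_w * np.exp(s),
                            minlength=data.n)
            return float(np.sum(1.0 - np.exp(-H)))

        # truth value uses the simulator's own baseline support
        data_truth = JointData.from_cohort(cohort, truth.survival.baseline)
        b_true = gt.b[[int(p[1:]) for p in cohort.patient_ids]]
        q_truth = event_load(data_truth, truth.longitudinal, truth.survival,
                             b_true)

        # posterior draws of the same functional: (theta, b) pairs from the
        # same MCMC iteration (kept index ib * b_thin of chain c)
        n_chains, n_keep = next(iter(draws.params.values())).shape
        b_thin = draws.config["b_thin"]
        n_b = draws.b_draws.shape[1]
        pairs = [(c * n_keep + ib * b_thin, c, ib)
                 for c in range(n_chains) for ib in range(n_b)]
        pairs = [pairs[i] for i in
                 np.linspace(0, len(pairs) - 1, 60).astype(int)]
        qs = []
        for j, c, ib in pairs:
            lp, sp = draws.draw_params(j)
            qs.append(event_load(data, lp, sp, draws.b_draws[c, ib]))
        lo, hi = np.quantile(qs, [0.025, 0.975])
        assert lo <= q_truth <= hi
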