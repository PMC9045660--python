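"""Landmark-window discrimination, bootstrap optimism correction, and the
static time-varying Cox comparator.

At landmark t with horizon dt, cases are subjects whose event falls in
(t, t+dt]; controls are subjects still under observation and event-free at
t+dt. The AUC is the proportion of case-control pairs ranked correctly by
the predicted window risk (ties half credit). Subjects censored inside the
window are excluded by default; an inverse-probability-of-censoring
weighted variant (Kaplan-Meier weights) is available.

Optimism correction follows Harrell's bootstrap: refit on a resample of
patients, score both the resample and the original cohort, and subtract the
mean gap from the apparent AUC.

The static comparator is a Cox proportional-hazards model with delayed
entry, baseline marker status, and segment length/esophagitis as step
functions (Efron ties, via lifelines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MARKERS, Cohort, standardized_age

__all__ = [
    "ValidationConfig",
    "ValidationResult",
    "CoxFit",
    "window_auc",
    "bootstrap_optimism",
    "joint_model_recipe",
    "fit_static_cox",
    "static_risk_scores",
]


@dataclass
class ValidationConfig:
    landmarks: tuple = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    horizon: float = 3.0
    n_bootstrap: int = 100
    censor_policy: str = "exclude"
    seed: int = 0

    def __post_init__(self):
        lm = list(self.landmarks)
        if any(t <= 0 for t in lm) or any(b <= a for a, b in zip(lm, lm[1:])):
            raise ValueError("landmarks must be positive and increasing")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")
        if self.censor_policy not in ("exclude", "ipcw"):
            raise ValueError("censor_policy must be 'exclude' or 'ipcw'")


@dataclass
class ValidationResult:
    """Per-landmark apparent/corrected AUCs for the dynamic model and the
    apparent AUC of the static comparator."""

    table: pd.DataFrame  # landmark, auc_apparent, optimism, auc_corrected, auc_static
    n_bootstrap: int
    n_failed_refits: int
    per_replicate: list = field(default_factory=list)


def _km_censoring_survival(outcomes):
    """Kaplan-Meier estimate of the censoring survival G(t)."""
    from lifelines import KaplanMeierFitter

    T = np.array([o.event_time_years for o in outcomes])
    cens = np.array([1 - o.event for o in outcomes])
    km = KaplanMeierFitter()
    km.fit(T, event_observed=cens)
    return lambda t: float(
        np.clip(km.survival_function_at_times(np.atleast_1d(t)).values[0],
                1e-6, 1.0)
    )


def window_auc(
    risks: dict,
    outcomes,
    t: float,
    horizon: float,
    policy: str = "exclude",
) -> float | None:
    """Pairwise window AUC at landmark t.

    ``risks`` maps patient id -> predicted window risk; only subjects at
    risk at t (event/censor time > t) are used. Returns None when there are
    no cases or no controls (undefined AUC at that landmark).
    """
    end = t + horizon
    by_id = {o.patient_id: o for o in outcomes}
    cases, controls = [], []
    case_w, control_w = [], []
    G = _km_censoring_survival(list(by_id.values())) if policy == "ipcw" else None
    for pid, r in risks.items():
        o = by_id[pid]
        if o.event_time_years <= t:
            continue  # not at risk at the landmark
        if o.event == 1 and o.event_time_years <= end:
            cases.append(float(r))
            case_w.append(1.0 / G(o.event_time_years) if G else 1.0)
        elif o.event_time_years > end:
            controls.append(float(r))
            control_w.append(1.0 / G(end) if G else 1.0)
        # censored inside the window: excluded from both groups

    if not cases or not controls:
        return None
    ca = np.asarray(cases)[:, None]
    co = np.asarray(controls)[None, :]
    w = np.asarray(case_w)[:, None] * np.asarray(control_w)[None, :]
    wins = np.where(ca > co, 1.0, np.where(ca == co, 0.5, 0.0))
    return float(np.sum(w * wins) / np.sum(w))


def bootstrap_optimism(
    cohort: Cohort,
    fit_recipe,
    config: ValidationConfig,
    static_scores: dict | None = None,
) -> ValidationResult:
    """Harrell optimism-corrected landmark AUCs.

    ``fit_recipe(cohort, seed)`` must return a deterministic scorer:
    ``scorer(cohort, landmark) -> {patient_id: window risk}`` over subjects
    at risk at the landmark. For each of ``config.n_bootstrap`` replicates,
    patients (clusters, never visits) are resampled with replacement, the
    recipe is refit, and optimism accumulates as AUC(boot-on-boot) minus
    AUC(boot-on-original). Replicates whose refit raises are dropped and
    counted. With ``n_bootstrap=0`` the corrected AUC equals the apparent.
    """
    rng = np.random.default_rng(config.seed)
    lms = list(config.landmarks)

    scorer = fit_recipe(cohort, config.seed)
    apparent = {
        t: window_auc(scorer(cohort, t), cohort.outcomes, t, config.horizon,
                      config.censor_policy)
        for t in lms
    }

    optim_sums = {t: 0.0 for t in lms}
    optim_counts = {t: 0 for t in lms}
    per_replicate = []
    n_failed = 0
    ids = cohort.patient_ids
    for rep in range(config.n_bootstrap):
        draw = rng.integers(0, len(ids), size=len(ids))
        boot = cohort.resample([ids[i] for i in draw])
        try:
            scorer_b = fit_recipe(boot, config.seed + 1 + rep)
        except Exception:
            n_failed += 1
            continue
        rep_row = {"replicate": rep}
        for t in lms:
            auc_bb = window_auc(scorer_b(boot, t), boot.outcomes, t,
                                config.horizon, config.censor_policy)
            auc_bo = window_auc(scorer_b(cohort, t), cohort.outcomes, t,
                                config.horizon, config.censor_policy)
            if auc_bb is not None and auc_bo is not None:
                optim_sums[t] += auc_bb - auc_bo
                optim_counts[t] += 1
            rep_row[f"auc_boot@{t}"] = auc_bb
            rep_row[f"auc_orig@{t}"] = auc_bo
        per_replicate.append(rep_row)

    rows = []
    for t in lms:
        app = apparent[t]
        opt = (optim_sums[t] / optim_counts[t]) if optim_counts[t] else 0.0
        rows.append({
            "landmark": t,
            "auc_apparent": app,
            "optimism": opt if app is not None else None,
            "auc_corrected": (app - opt) if app is not None else None,
            "auc_static": (
                window_auc(static_scores, cohort.outcomes, t, config.horizon,
                           config.censor_policy)
                if static_scores is not None else None
            ),
        })
    return ValidationResult(
        table=pd.DataFrame(rows).set_index("landmark"),
        n_bootstrap=config.n_bootstrap,
        n_failed_refits=n_failed,
        per_replicate=per_replicate,
    )


def joint_model_recipe(sampler_config, n_outer: int = 60, n_inner: int = 80,
                       horizon: float = 3.0):
    """Fit recipe for :func:`bootstrap_optimism` that refits the joint model
    and scores window risks by dynamic prediction.

    The returned recipe is ``recipe(cohort, seed) -> scorer``;
    ``scorer(cohort, t)`` computes P(T <= t + horizon | T > t, history up to
    t) for every subject at risk at t, from their truncated history.
    ``n_outer``/``n_inner`` trade Monte-Carlo accuracy for speed (ranks are
    all the AUC needs).
    """
    from dataclasses import replace as _dc_replace

    from .jointmodel import fit_joint_model
    from .predict import PatientHistory, dynamic_risk

    def recipe(cohort: Cohort, seed: int):
        cfg = _dc_replace(sampler_config, seed=seed)
        draws = fit_joint_model(cohort, cfg)

        def scorer(target: Cohort, t: float):
            risks = {}
            for b in target.baselines:
                o = target.outcome_of(b.patient_id)
                if o.event_time_years <= t:
                    continue
                hist = PatientHistory(
                    age_years=b.age_years, female=b.female,
                    visits=[v for v in target.visits_of(b.patient_id)
                            if v.time_years <= t],
                )
                pred = dynamic_risk(hist, t, horizon, draws,
                                    seed=seed + int(round(1000 * t)),
                                    n_outer=n_outer, n_inner=n_inner)
                risks[b.patient_id] = pred.risk
            return risks

        return scorer

    return recipe


@dataclass
class CoxFit:
    """Static Cox comparator: coefficients with Wald 95% CIs."""

    names: tuple
    coefs: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    loglik: float
    ties: str
    n_missing_baseline_markers: int
    age_scaler: tuple
    penalizer: float = 0.0

    def hazard_ratios(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hr": np.exp(self.coefs),
            "ci_lower": np.exp(self.ci_lower),
            "ci_upper": np.exp(self.ci_upper),
        }, index=list(self.names))


_COX_COLS = ("age_std", "female", "long_segment", "esophagitis",
             "lgd0", "p530", "sox20")


def _cox_long_table(cohort: Cohort):
    """Start-stop rows: one per covariate interval inside (entry, T]."""
    rows = []
    n_missing = 0
    for b in cohort.baselines:
        pid = b.patient_id
        o = cohort.outcome_of(pid)
        vs = cohort.visits_of(pid)
        base = vs[0]
        markers0 = []
        for m in MARKERS:
            val = base.marker(m)
            if math.isnan(val):
                n_missing += 1
                val = 0.0  # missing baseline marker treated as normal
            markers0.append(val)
        a = standardized_age(cohort, b.age_years)
        starts = [v.time_years for v in vs]
        for j, v in enumerate(vs):
            lo = max(starts[j], o.entry_time_years)
            hi = starts[j + 1] if j + 1 < len(vs) else o.event_time_years
            hi = min(hi, o.event_time_years)
            if hi <= lo:
                continue
            rows.append({
                "id": pid, "start": lo, "stop": hi,
                "event": int(o.event == 1 and hi == o.event_time_years),
                "age_std": a, "female": b.female,
                "long_segment": v.long_segment, "esophagitis": v.esophagitis,
                "lgd0": markers0[0], "p530": markers0[1], "sox20": markers0[2],
            })
    return pd.DataFrame(rows), n_missing


def fit_static_cox(cohort: Cohort, marker_source: str = "baseline",
                   covariates: tuple = _COX_COLS) -> CoxFit:
    """Cox proportional-hazards comparator on baseline marker status.

    Default covariates: standardized age, gender, baseline LGD/p53/SOX2
    (missing treated as normal, with a count reported), and segment length
    and esophagitis as time-varying step functions; ``covariates`` can
    restrict the design (e.g. when a column is constant in a small cohort).
    Efron tie handling and delayed entry at the run-in boundary, via
    lifelines' ``CoxTimeVaryingFitter``.
    """
    if marker_source != "baseline":
        raise ValueError("only marker_source='baseline' is implemented")
    if cohort.age_scaler is None:
        raise ValueError("cohort must be age-standardized")
    from lifelines import CoxTimeVaryingFitter
    from lifelines.exceptions import ConvergenceError

    unknown = [c for c in covariates if c not in _COX_COLS]
    if unknown:
        raise ValueError(f"unknown covariates {unknown}")
    df, n_missing = _cox_long_table(cohort)
    df = df[["id", "start", "stop", "event", *covariates]]
    penalizer = 0.0
    ctv = None
    for penalizer in (0.0, 0.1):
        ctv = CoxTimeVaryingFitter(penalizer=penalizer)
        try:
            ctv.fit(df, id_col="id", start_col="start", stop_col="stop",
                    event_col="event", show_progress=False)
            break
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            # sparse baseline markers can separate small cohorts; retry with
            # a light ridge before giving up
            if penalizer > 0.0:
                raise RuntimeError(
                    f"static Cox fit failed to converge: {exc}") from exc

    names = tuple(ctv.params_.index)
    coefs = ctv.params_.values
    se = ctv.standard_errors_.values
    z = 1.959963984540054
    return CoxFit(
        names=names,
        coefs=coefs,
        se=se,
        ci_lower=coefs - z * se,
        ci_upper=coefs + z * se,
        loglik=float(ctv.log_likelihood_),
        ties="efron",
        n_missing_baseline_markers=n_missing,
        age_scaler=cohort.age_scaler,
        penalizer=penalizer,
    )


def static_risk_scores(fit: CoxFit, cohort: Cohort) -> dict:
    """Baseline linear predictor per patient (risk ranking for the AUC).

    Uses each patient's index-visit covariates; missing baseline markers
    are treated as normal, matching the fit.
    """
    scores = {}
    coef = dict(zip(fit.names, fit.coefs))
    mean, sd = fit.age_scaler
    for b in cohort.baselines:
        v0 = cohort.visits_of(b.patient_id)[0]
        x = {
            "age_std": (b.age_years - mean) / sd,
            "female": b.female,
            "long_segment": v0.long_segment,
            "esophagitis": v0.esophagitis,
            "lgd0": 0.0 if math.isnan(v0.lgd) else v0.lgd,
            "p530": 0.0 if math.isnan(v0.p53) else v0.p53,
            "sox20": 0.0 if math.isnan(v0.sox2) else v0.sox2,
        }
        scores[b.patient_id] = float(sum(coef[k] * x[k] for k in coef))
    return scores
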