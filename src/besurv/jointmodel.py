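"""Multivariate joint model: likelihood, MCMC fitting, and hazard-ratio reporting.

Three random-intercept logistic submodels (LGD, p53, SOX2) share a trivariate
normal random-intercept vector b_i ~ N(0, D) and drive a time-varying
proportional-hazards model for HGD/EAC through current-value and
accumulated-effect associations (see :mod:`besurv.hazard`). The posterior is
explored by an adaptive Metropolis-within-Gibbs sampler with block updates
for each submodel's fixed effects, the survival coefficients, the
piecewise-constant baseline log-rates, the per-patient intercepts, and D.

Priors: N(0, 10^2) on all fixed effects, survival coefficients,
associations and baseline log-rates; half-t(3, 2.5) on the random-intercept
sds; uniform over valid correlation matrices for the correlation part of D.

Association coefficients are reported as hazard ratios per 10% change in
the probability of aberrant expression, HR = exp(0.1 * alpha).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from ._likelihood import JointData
from .cohort import MARKERS, Cohort
from .hazard import BaselineHazard, SurvivalParams
from .longitudinal import (
    COVARIATE_NAMES,
    LongitudinalParams,
    SeparationError,
    fit_mixed_logistic,
)

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "joint_log_likelihood",
    "fit_joint_model",
    "hazard_ratio_per_10pct",
    "illustrative_risk_contribution",
]

SURV_NAMES = ("age_std", "female", "long_segment", "esophagitis")
_PRIOR_SD = 10.0
_HALF_T_DF = 3.0
_HALF_T_SCALE = 2.5


@dataclass
class SamplerConfig:
    """MCMC settings; all randomness flows from ``seed`` (chain c uses seed+c)."""

    n_chains: int = 2
    n_iter: int = 6000
    n_burn: int = 1000
    thin: int = 1
    seed: int = 0
    n_intervals: int = 5
    association_scale: str = "probability"
    estimate_value: bool = True
    estimate_cumulative: bool = True
    prior_only: bool = False
    init_from_separate_fits: bool = True
    b_thin: int = 5
    adapt_window: int = 25

    def to_dict(self) -> dict:
        return asdict(self)


def joint_log_likelihood(
    cohort: Cohort,
    long_params: LongitudinalParams,
    surv_params: SurvivalParams,
    b: np.ndarray,
) -> float:
    """Data log-likelihood: Bernoulli observation terms plus
    ``event * log h(T_i) - H(entry_i, T_i)`` per patient, given intercepts
    ``b`` (n x 3, cohort patient order). Missing marker values contribute
    nothing; the N(0, D) density of b is *not* included.
    """
    if cohort.n_patients == 0:
        return 0.0
    b = np.asarray(b, dtype=float).reshape(cohort.n_patients, 3)
    data = JointData.from_cohort(cohort, surv_params.baseline)
    ll = data.loglik(long_params, surv_params, b, per_patient=True)
    if not np.all(np.isfinite(ll)):
        bad = [data.patient_ids[i] for i in np.where(~np.isfinite(ll))[0]]
        raise FloatingPointError(
            f"non-finite likelihood contribution for patients {bad}"
        )
    return float(ll.sum())


def hazard_ratio_per_10pct(alpha):
    """HR for a 10% shift in the probability of aberrant expression."""
    return np.exp(0.1 * np.asarray(alpha, dtype=float))


def illustrative_risk_contribution(prob_aberrant: float, hr_value: float) -> float:
    """Single-marker back-of-envelope risk contribution: probability of
    aberrant expression times the marker's value hazard ratio.

    This reproduces the clinical illustration of how one marker's estimated
    probability scales its hazard-ratio contribution; it is *not* the
    model-based window risk (see :mod:`besurv.predict` for that).
    """
    if not 0.0 <= prob_aberrant <= 1.0:
        raise ValueError("prob_aberrant must be a probability")
    return prob_aberrant * hr_value


# ----------------------------------------------------------------------
# prior densities (unnormalized)

def _logp_normal(x, sd=_PRIOR_SD):
    x = np.asarray(x, dtype=float)
    return float(-0.5 * np.sum((x / sd) ** 2))


def _logp_half_t(s):
    # half-t(3, 2.5) on a positive sd
    return float(-0.5 * (_HALF_T_DF + 1) * np.sum(
        np.log1p((np.asarray(s) / _HALF_T_SCALE) ** 2 / _HALF_T_DF)
    ))


def _corr_from_z(z):
    r = np.tanh(np.asarray(z, dtype=float))
    R = np.array([
        [1.0, r[0], r[1]],
        [r[0], 1.0, r[2]],
        [r[1], r[2], 1.0],
    ])
    return R, r


def _logp_D(log_s, z):
    """log prior of (log sds, atanh correlations), with transform Jacobians;
    -inf when the correlation matrix is not positive definite."""
    s = np.exp(log_s)
    R, r = _corr_from_z(z)
    if np.min(np.linalg.eigvalsh(R)) <= 1e-10:
        return -np.inf, None
    lp = _logp_half_t(s) + float(np.sum(log_s))        # half-t + ds/dlog s
    lp += float(np.sum(np.log1p(-r ** 2)))             # dr/dz = 1 - r^2
    D = R * np.outer(s, s)
    return lp, D


def _mvn_logpdf(b, D):
    """Rows of b under N(0, D); returns per-row values."""
    L = np.linalg.cholesky(D)
    sol = np.linalg.solve(L, b.T)
    quad = np.sum(sol ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (quad + logdet + 3 * math.log(2 * math.pi))


# ----------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """MCMC output: per-scalar draws, thinned random-intercept draws, and
    convergence diagnostics (split R-hat, effective sample size)."""

    params: dict  # name -> (n_chains, n_draws)
    b_draws: np.ndarray  # (n_chains, n_b, n_patients, 3)
    knots: np.ndarray
    association_scale: str
    age_scaler: tuple
    patient_ids: list
    seed: int
    config: dict
    rhat: dict
    ess: dict
    converged: bool
    acceptance: dict

    @property
    def n_draws(self) -> int:
        first = next(iter(self.params.values()))
        return int(first.shape[0] * first.shape[1])

    def stacked(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def _stack_block(self, names):
        return np.column_stack([self.stacked(n) for n in names])

    def draw_params(self, j: int):
        """Reconstruct (LongitudinalParams, SurvivalParams) for flat draw j."""
        beta = {
            m: np.array([
                self.stacked(f"beta[{m},{c}]")[j] for c in COVARIATE_NAMES
            ])
            for m in MARKERS
        }
        s = np.array([self.stacked(f"sd_b[{m}]")[j] for m in MARKERS])
        r = [self.stacked(f"corr[{p}]")[j]
             for p in ("lgd,p53", "lgd,sox2", "p53,sox2")]
        R = np.array([[1, r[0], r[1]], [r[0], 1, r[2]], [r[1], r[2], 1.0]])
        D = R * np.outer(s, s)
        long_params = LongitudinalParams(beta=beta, D=D)
        K = len(self.knots) - 1
        surv = SurvivalParams(
            baseline=BaselineHazard(
                knots=self.knots,
                log_rates=np.array([
                    self.stacked(f"log_rate[{i}]")[j] for i in range(K)
                ]),
            ),
            gamma=np.array([self.stacked(f"gamma[{c}]")[j] for c in SURV_NAMES]),
            alpha_value=np.array([
                self.stacked(f"alpha_value[{m}]")[j] for m in MARKERS
            ]),
            alpha_cumulative=np.array([
                self.stacked(f"alpha_cumulative[{m}]")[j] for m in MARKERS
            ]),
            association_scale=self.association_scale,
        )
        return long_params, surv

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.params:
            x = self.stacked(name)
            rows.append({
                "param": name,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)),
                "median": float(np.median(x)),
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
                "rhat": self.rhat.get(name, np.nan),
                "ess": self.ess.get(name, np.nan),
            })
        return pd.DataFrame(rows).set_index("param")

    def hazard_ratio_table(self) -> pd.DataFrame:
        """Hazard-ratio table: covariate HRs exp(gamma) and per-marker
        value / accumulated-effect HRs per 10% (median, 95% CrI, and the
        posterior probability of HR > 1)."""
        rows = []

        def add(label, hr_draws):
            rows.append({
                "term": label,
                "hr": float(np.median(hr_draws)),
                "ci_lower": float(np.quantile(hr_draws, 0.025)),
                "ci_upper": float(np.quantile(hr_draws, 0.975)),
                "p_hr_gt_1": float(np.mean(hr_draws > 1.0)),
            })

        for c in SURV_NAMES:
            add(c, np.exp(self.stacked(f"gamma[{c}]")))
        for m in MARKERS:
            add(f"{m}:value",
                hazard_ratio_per_10pct(self.stacked(f"alpha_value[{m}]")))
            add(f"{m}:accumulated",
                hazard_ratio_per_10pct(self.stacked(f"alpha_cumulative[{m}]")))
        return pd.DataFrame(rows).set_index("term")

    def save(self, path) -> None:
        """Columnar draw store (.npz) plus JSON metadata side-car."""
        path = str(path)
        np.savez_compressed(
            path if path.endswith(".npz") else path + ".npz",
            b_draws=self.b_draws,
            knots=self.knots,
            **{f"par::{k}": v for k, v in self.params.items()},
        )
        meta = {
            "association_scale": self.association_scale,
            "age_scaler": list(self.age_scaler),
            "patient_ids": list(self.patient_ids),
            "seed": self.seed,
            "config": self.config,
            "rhat": {k: (None if not np.isfinite(v) else float(v))
                     for k, v in self.rhat.items()},
            "ess": {k: (None if not np.isfinite(v) else float(v))
                    for k, v in self.ess.items()},
            "converged": self.converged,
            "acceptance": self.acceptance,
        }
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        with np.load(base + ".npz") as z:
            params = {k[5:]: z[k] for k in z.files if k.startswith("par::")}
            b_draws = z["b_draws"]
            knots = z["knots"]
        with open(base + ".meta.json") as fh:
            meta = json.load(fh)
        return cls(
            params=params,
            b_draws=b_draws,
            knots=knots,
            association_scale=meta["association_scale"],
            age_scaler=tuple(meta["age_scaler"]),
            patient_ids=meta["patient_ids"],
            seed=meta["seed"],
            config=meta["config"],
            rhat={k: (np.nan if v is None else v) for k, v in meta["rhat"].items()},
            ess={k: (np.nan if v is None else v) for k, v in meta["ess"].items()},
            converged=meta["converged"],
            acceptance=meta["acceptance"],
        )


# ----------------------------------------------------------------------

class _Block:
    """Adaptive Metropolis proposal for one update block.

    During burn-in the scalar step size chases a ~25% acceptance rate and,
    once enough history accumulates, the proposal covariance switches to
    the empirical covariance of the visited states (Haario-style); both are
    frozen after burn-in so the kept chain is Markov.
    """

    def __init__(self, dim: int, scale: float, window: int):
        self.dim = dim
        self.scale = scale
        self.window = window
        self.n = 0
        self.acc = 0
        self.hist: list = []
        self.chol = None

    def propose(self, x: np.ndarray, rng) -> np.ndarray:
        eps = rng.standard_normal(self.dim)
        if self.chol is not None:
            return x + self.scale * (self.chol @ eps)
        return x + self.scale * eps

    def record(self, accepted: bool, x: np.ndarray, adapting: bool):
        if not adapting:
            return
        self.n += 1
        self.acc += accepted
        self.hist.append(np.array(x, dtype=float))
        if self.n % self.window == 0:
            rate = self.acc / self.n
            self.scale *= math.exp((rate - 0.25) * 0.5)
            self.n = 0
            self.acc = 0
            if len(self.hist) >= 60 * max(1, self.dim // 2):
                arr = np.array(self.hist[-600:])
                C = np.cov(arr.T) + 1e-8 * np.eye(self.dim)
                try:
                    chol = np.linalg.cholesky(C)
                except np.linalg.LinAlgError:
                    return
                if self.chol is None:
                    self.scale = 2.38 / math.sqrt(self.dim)
                self.chol = chol


class _ChainState:
    def __init__(self, data: JointData, config: SamplerConfig, init: dict,
                 rng: np.random.Generator):
        self.data = data
        self.cfg = config
        self.rng = rng
        self.lw = 0.0 if config.prior_only else 1.0
        self.beta = init["beta"].copy()          # (3, 6)
        self.gamma = init["gamma"].copy()        # (4,)
        self.av = init["alpha_value"].copy()     # (3,)
        self.ac = init["alpha_cum"].copy()       # (3,)
        self.logl = init["log_rates"].copy()     # (K,)
        self.log_s = init["log_s"].copy()        # (3,)
        self.z = init["z"].copy()                # (3,)
        _, self.D = _logp_D(self.log_s, self.z)
        self.b = init["b"].copy()                # (n, 3)

        w = config.adapt_window
        K = len(self.logl)
        self.blocks = {
            **{f"beta{k}": _Block(6, 0.08, w) for k in range(3)},
            "gamma": _Block(4, 0.1, w),
            **{f"alpha{k}": _Block(2, 0.15, w) for k in range(3)},
            "logl": _Block(K, 0.15, w),
            "surv_joint": _Block(10 + K, 0.03, w),
            "D": _Block(6, 0.1, w),
        }
        self.b_scale = np.full(data.n, 0.5)
        self.b_acc = np.zeros(data.n)
        self.b_n = 0

        self._refresh_all()

    # -------------- cached likelihood pieces --------------
    def _refresh_all(self):
        if self.lw == 0.0:
            self.marker_nodes = [None] * 3
            self.bern = np.zeros(3)
            self.surv = 0.0
            return
        self.marker_nodes = [
            self.data.marker_process(k, self.beta[k], self.b[:, k],
                                     self.cfg.association_scale)
            for k in range(3)
        ]
        self.bern = np.array([
            self.data.bernoulli_loglik(k, self.beta[k], self.b[:, k])
            for k in range(3)
        ])
        self.surv = self._surv()

    def _surv(self, marker_nodes=None, logl=None, gamma=None, av=None, ac=None,
              per_patient=False):
        if self.lw == 0.0:
            return np.zeros(self.data.n) if per_patient else 0.0
        return self.data.survival_loglik(
            self.logl if logl is None else logl,
            self.gamma if gamma is None else gamma,
            self.av if av is None else av,
            self.ac if ac is None else ac,
            self.marker_nodes if marker_nodes is None else marker_nodes,
            per_patient=per_patient,
        )

    # -------------- block updates --------------
    def update_beta(self, adapting: bool):
        for k in range(3):
            blk = self.blocks[f"beta{k}"]
            prop = blk.propose(self.beta[k], self.rng)
            if self.lw == 0.0:
                new_nodes, new_bern, new_surv = None, 0.0, 0.0
                cur_bern, cur_surv = 0.0, 0.0
            else:
                new_nodes = self.data.marker_process(
                    k, prop, self.b[:, k], self.cfg.association_scale)
                mn = list(self.marker_nodes)
                mn[k] = new_nodes
                new_bern = self.data.bernoulli_loglik(k, prop, self.b[:, k])
                new_surv = self._surv(marker_nodes=mn)
                cur_bern, cur_surv = self.bern[k], self.surv
            lr = (new_bern + new_surv + _logp_normal(prop)
                  - cur_bern - cur_surv - _logp_normal(self.beta[k]))
            acc = math.log(self.rng.random()) < lr
            if acc:
                self.beta[k] = prop
                if self.lw != 0.0:
                    self.marker_nodes[k] = new_nodes
                    self.bern[k] = new_bern
                    self.surv = new_surv
            blk.record(acc, self.beta[k], adapting)

    def update_gamma(self, adapting: bool):
        blk = self.blocks["gamma"]
        prop = blk.propose(self.gamma, self.rng)
        new_surv = self._surv(gamma=prop)
        lr = new_surv + _logp_normal(prop) - self.surv - _logp_normal(self.gamma)
        acc = math.log(self.rng.random()) < lr
        if acc:
            self.gamma = prop
            self.surv = new_surv
        blk.record(acc, self.gamma, adapting)

    def update_alpha(self, adapting: bool):
        mask = np.array([self.cfg.estimate_value, self.cfg.estimate_cumulative],
                        dtype=float)
        for k in range(3):
            blk = self.blocks[f"alpha{k}"]
            cur = np.array([self.av[k], self.ac[k]])
            prop = cur + mask * (blk.propose(cur, self.rng) - cur)
            av, ac = self.av.copy(), self.ac.copy()
            av[k], ac[k] = prop
            new_surv = self._surv(av=av, ac=ac)
            lr = (new_surv + _logp_normal(av) + _logp_normal(ac)
                  - self.surv - _logp_normal(self.av) - _logp_normal(self.ac))
            acc = math.log(self.rng.random()) < lr
            if acc:
                self.av, self.ac = av, ac
                self.surv = new_surv
            blk.record(acc, np.array([self.av[k], self.ac[k]]), adapting)

    def update_surv_joint(self, adapting: bool):
        """Joint update of (gamma, alpha_value, alpha_cum, log-rates):
        the accumulated associations trade off against the baseline's time
        shape, a correlation only a joint adapted proposal can follow."""
        blk = self.blocks["surv_joint"]
        mask = np.concatenate([
            np.ones(4),
            np.full(3, float(self.cfg.estimate_value)),
            np.full(3, float(self.cfg.estimate_cumulative)),
            np.ones(len(self.logl)),
        ])
        cur = np.concatenate([self.gamma, self.av, self.ac, self.logl])
        prop = cur + mask * (blk.propose(cur, self.rng) - cur)
        g, av, ac, logl = (prop[:4], prop[4:7], prop[7:10], prop[10:])
        new_surv = self._surv(logl=logl, gamma=g, av=av, ac=ac)
        lr = (new_surv + _logp_normal(prop)
              - self.surv - _logp_normal(cur))
        acc = math.log(self.rng.random()) < lr
        if acc:
            self.gamma, self.av, self.ac, self.logl = g, av, ac, logl
            self.surv = new_surv
        blk.record(
            acc, np.concatenate([self.gamma, self.av, self.ac, self.logl]),
            adapting,
        )

    def update_log_rates(self, adapting: bool):
        blk = self.blocks["logl"]
        prop = blk.propose(self.logl, self.rng)
        new_surv = self._surv(logl=prop)
        lr = new_surv + _logp_normal(prop) - self.surv - _logp_normal(self.logl)
        acc = math.log(self.rng.random()) < lr
        if acc:
            self.logl = prop
            self.surv = new_surv
        blk.record(acc, self.logl, adapting)

    def _per_patient_ll(self, b, marker_nodes=None):
        """Data ll per patient for intercepts b (reusing marker caches when
        they match b), plus log N(b; 0, D)."""
        if self.lw == 0.0:
            return _mvn_logpdf(b, self.D), None
        if marker_nodes is None:
            marker_nodes = [
                self.data.marker_process(k, self.beta[k], b[:, k],
                                         self.cfg.association_scale)
                for k in range(3)
            ]
        ll = self._surv(marker_nodes=marker_nodes, per_patient=True).copy()
        for k in range(3):
            ll += self.data.bernoulli_loglik(k, self.beta[k], b[:, k],
                                             per_patient=True)
        return ll + _mvn_logpdf(b, self.D), marker_nodes

    def update_b(self, adapting: bool):
        n = self.data.n
        cur_ll, _ = self._per_patient_ll(self.b, marker_nodes=self.marker_nodes)
        L = np.linalg.cholesky(self.D)
        eps = self.rng.standard_normal((n, 3)) @ L.T
        prop = self.b + self.b_scale[:, None] * eps
        prop_ll, prop_nodes = self._per_patient_ll(prop)
        accept = np.log(self.rng.random(n)) < prop_ll - cur_ll
        if np.any(accept):
            self.b = np.where(accept[:, None], prop, self.b)
            if self.lw == 0.0:
                pass
            else:
                # splice accepted patients' cached marker nodes instead of
                # recomputing all three processes from scratch
                acc_node = accept[self.data.node_pat]
                acc_ev = (accept[self.data.ev_pat]
                          if len(self.data.ev_t) else np.zeros(0, bool))
                merged = []
                for k in range(3):
                    cv, cI, cve, cIe = self.marker_nodes[k]
                    pv, pI, pve, pIe = prop_nodes[k]
                    merged.append((
                        np.where(acc_node, pv, cv),
                        np.where(acc_node, pI, cI),
                        np.where(acc_ev, pve, cve) if len(cve) else cve,
                        np.where(acc_ev, pIe, cIe) if len(cIe) else cIe,
                    ))
                self.marker_nodes = merged
                self.bern = np.array([
                    self.data.bernoulli_loglik(k, self.beta[k], self.b[:, k])
                    for k in range(3)
                ])
                self.surv = self._surv()
        self.b_acc += accept
        self.b_n += 1
        if adapting and self.b_n % self.cfg.adapt_window == 0:
            rate = self.b_acc / self.b_n
            self.b_scale *= np.exp((rate - 0.3) * 0.5)
            self.b_acc[:] = 0
            self.b_n = 0

    def update_D(self, adapting: bool):
        blk = self.blocks["D"]
        cur = np.concatenate([self.log_s, self.z])
        prop = blk.propose(cur, self.rng)
        prop_ls, prop_z = prop[:3], prop[3:]
        lp_new, D_new = _logp_D(prop_ls, prop_z)
        acc = False
        if np.isfinite(lp_new):
            lp_cur, _ = _logp_D(self.log_s, self.z)
            lr = (lp_new + float(np.sum(_mvn_logpdf(self.b, D_new)))
                  - lp_cur - float(np.sum(_mvn_logpdf(self.b, self.D))))
            acc = math.log(self.rng.random()) < lr
        if acc:
            self.log_s, self.z, self.D = prop_ls, prop_z, D_new
        blk.record(acc, np.concatenate([self.log_s, self.z]), adapting)

    def step(self, adapting: bool):
        self.update_beta(adapting)
        # survival-only blocks are cheap; extra sweeps help the strongly
        # correlated value/accumulated associations mix
        for _ in range(2):
            self.update_gamma(adapting)
            self.update_alpha(adapting)
            self.update_log_rates(adapting)
        for _ in range(4):
            self.update_surv_joint(adapting)
        self.update_b(adapting)
        self.update_D(adapting)
        self.update_b(adapting)
        self.update_D(adapting)

    def scalars(self) -> np.ndarray:
        r = np.tanh(self.z)
        return np.concatenate([
            self.beta.ravel(), self.gamma, self.av, self.ac, self.logl,
            np.exp(self.log_s), r,
        ])


def _scalar_names(K: int):
    names = []
    for m in MARKERS:
        names += [f"beta[{m},{c}]" for c in COVARIATE_NAMES]
    names += [f"gamma[{c}]" for c in SURV_NAMES]
    names += [f"alpha_value[{m}]" for m in MARKERS]
    names += [f"alpha_cumulative[{m}]" for m in MARKERS]
    names += [f"log_rate[{i}]" for i in range(K)]
    names += [f"sd_b[{m}]" for m in MARKERS]
    names += ["corr[lgd,p53]", "corr[lgd,sox2]", "corr[p53,sox2]"]
    return names


def _initial_values(cohort: Cohort, data: JointData, config: SamplerConfig):
    beta = np.zeros((3, 6))
    log_s = np.zeros(3)
    if config.init_from_separate_fits and not config.prior_only:
        for k, m in enumerate(MARKERS):
            try:
                fit = fit_mixed_logistic(cohort, m)
                beta[k] = fit.estimates
                log_s[k] = math.log(max(fit.sigma_b, 0.05))
            except (SeparationError, ValueError):
                ybar = (float(data.y_obs[k].mean())
                        if len(data.y_obs[k]) else 0.1)
                beta[k, 0] = special.logit(min(max(ybar, 1e-3), 1 - 1e-3))
    events = float(data.delta.sum())
    py = float(np.sum(data.T - data.entry))
    rate = max(events, 0.5) / max(py, 1e-9)
    K = data.baseline_template.n_intervals
    return {
        "beta": beta,
        "gamma": np.zeros(4),
        "alpha_value": np.zeros(3),
        "alpha_cum": np.zeros(3),
        "log_rates": np.full(K, math.log(rate)),
        "log_s": log_s,
        "z": np.zeros(3),
        "b": np.zeros((data.n, 3)),
    }


def fit_joint_model(cohort: Cohort, config: SamplerConfig) -> PosteriorDraws:
    """Fit the multivariate joint model by adaptive Metropolis-within-Gibbs.

    Requires an eligibility-filtered, age-standardized cohort with at least
    one event. Identical ``config`` (including seed) gives identical draws.
    A fit with any split R-hat above 1.1 is returned flagged
    ``converged=False``, never discarded.
    """
    import arviz as az

    if cohort.age_scaler is None:
        raise ValueError("cohort must be age-standardized (standardize_age)")
    event_times = np.array(
        [o.event_time_years for o in cohort.outcomes if o.event == 1]
    )
    if len(event_times) < 1 and not config.prior_only:
        raise ValueError("joint model requires at least one event")
    horizon = float(max(o.event_time_years for o in cohort.outcomes)) + 10.0
    baseline = BaselineHazard.from_event_times(
        event_times, n_intervals=config.n_intervals, t_start=0.0,
        horizon=horizon,
    )
    data = JointData.from_cohort(cohort, baseline)
    init = _initial_values(cohort, data, config)

    K = baseline.n_intervals
    names = _scalar_names(K)
    n_keep = (config.n_iter - config.n_burn) // config.thin
    if n_keep <= 0:
        raise ValueError("n_iter must exceed n_burn")
    draws = np.empty((config.n_chains, n_keep, len(names)))
    n_b = len(range(0, n_keep, config.b_thin))
    b_draws = np.empty((config.n_chains, n_b, data.n, 3))
    acceptance = {}

    for c in range(config.n_chains):
        rng = np.random.default_rng(config.seed + c)
        chain = _ChainState(data, config, init, rng)
        kept = 0
        bkept = 0
        for it in range(config.n_iter):
            chain.step(adapting=it < config.n_burn)
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
                draws[c, kept] = chain.scalars()
                if kept % config.b_thin == 0:
                    b_draws[c, bkept] = chain.b
                    bkept += 1
                kept += 1
        acceptance[f"chain{c}"] = {
            name: (blk.acc / blk.n if blk.n else None)
            for name, blk in chain.blocks.items()
        }

    params = {name: draws[:, :, j] for j, name in enumerate(names)}
    rhat, ess = {}, {}
    for name, arr in params.items():
        if arr.shape[0] == 1:  # split a single chain in two for split-R-hat
            half = (arr.shape[1] // 2) * 2
            arr = arr[0, :half].reshape(2, -1)
        ds = az.convert_to_dataset({"x": arr})
        rhat[name] = float(az.rhat(ds)["x"].values)
        ess[name] = float(az.ess(ds)["x"].values)
    # constant scalars (e.g. an association switched off) have undefined
    # R-hat; only finite values above 1.1 flag non-convergence
    converged = all(
        (not np.isfinite(v)) or v <= 1.1 for v in rhat.values()
    )

    return PosteriorDraws(
        params=params,
        b_draws=b_draws,
        knots=baseline.knots,
        association_scale=config.association_scale,
        age_scaler=cohort.age_scaler,
        patient_ids=list(cohort.patient_ids),
        seed=config.seed,
        config=config.to_dict(),
        rhat=rhat,
        ess=ess,
        converged=converged,
        acceptance=acceptance,
    )
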