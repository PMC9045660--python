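"""Vectorized joint-likelihood engine.

Flattens a cohort into padded/flat arrays so a full joint log-likelihood
evaluation — Bernoulli terms for every non-missing marker observation plus
event terms with Gauss-Legendre cumulative hazards — is a handful of numpy
operations. Step covariates (segment length, esophagitis) are piecewise
constant between visits, so within each covariate interval the marker
linear predictor is affine in time and the accumulated probability integral
is closed-form (softplus differences; see :mod:`besurv.hazard`).

Internal module: the public surface re-exports through
:mod:`besurv.jointmodel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .cohort import MARKERS, Cohort, standardized_age
from .hazard import (
    BaselineHazard,
    SurvivalParams,
    expit_time_integral,
    gauss_legendre_nodes,
    linear_time_integral,
)
from .longitudinal import N_FIXED, design_row

_BETA5_COLS = np.array([0, 2, 3, 4, 5])  # fixed effects excluding time
_GL = 15


def _bern_loglik(eta, y):
    return y * eta - np.logaddexp(0.0, eta)


@dataclass
class JointData:
    """Precomputed design for fast joint-likelihood evaluation."""

    n: int
    patient_ids: list
    # Bernoulli observations per marker
    X_obs: list  # 3 arrays (n_k, 6)
    y_obs: list
    pat_obs: list
    # step-covariate intervals, flat across patients (grouped, in order)
    iv_ptr: np.ndarray  # (n+1,)
    iv_pat: np.ndarray  # (M,)
    iv_start: np.ndarray
    iv_end: np.ndarray
    iv_x5: np.ndarray  # (M, 5): 1, age_std, female, long_segment, esophagitis
    # quadrature nodes for H(entry, T_i)
    node_t: np.ndarray
    node_w: np.ndarray
    node_pat: np.ndarray
    node_seg: np.ndarray
    node_iv: np.ndarray
    node_w4: np.ndarray  # (F, 4) survival covariates at nodes
    # event terms
    delta: np.ndarray  # (n,)
    T: np.ndarray
    entry: np.ndarray
    ev_pat: np.ndarray
    ev_t: np.ndarray
    ev_seg: np.ndarray
    ev_iv: np.ndarray
    ev_w4: np.ndarray
    baseline_template: BaselineHazard

    @classmethod
    def from_cohort(cls, cohort: Cohort, baseline: BaselineHazard) -> "JointData":
        if cohort.age_scaler is None:
            raise ValueError("cohort must be age-standardized")
        ids = cohort.patient_ids
        idx = {pid: i for i, pid in enumerate(ids)}
        n = len(ids)

        age_std = np.array(
            [standardized_age(cohort, b.age_years) for b in cohort.baselines]
        )
        female = np.array([b.female for b in cohort.baselines], dtype=float)
        T = np.zeros(n)
        delta = np.zeros(n)
        entry = np.zeros(n)
        for o in cohort.outcomes:
            i = idx[o.patient_id]
            T[i], delta[i], entry[i] = o.event_time_years, o.event, o.entry_time_years
        if np.any(T <= entry):
            bad = [ids[i] for i in np.where(T <= entry)[0]]
            raise ValueError(f"follow-up does not exceed entry time for {bad}")

        # group visits per patient (already time-sorted by validation)
        visits_by = {pid: [] for pid in ids}
        for v in cohort.visits:
            visits_by[v.patient_id].append(v)

        X_obs = [[] for _ in MARKERS]
        y_obs = [[] for _ in MARKERS]
        pat_obs = [[] for _ in MARKERS]

        iv_ptr = [0]
        iv_pat, iv_start, iv_end, iv_x5 = [], [], [], []
        node_t, node_w, node_pat, node_seg, node_iv, node_w4 = [], [], [], [], [], []
        ev_pat, ev_t, ev_seg, ev_iv, ev_w4 = [], [], [], [], []

        knots = baseline.knots
        for i, pid in enumerate(ids):
            vs = visits_by[pid]
            starts = np.array([v.time_years for v in vs])
            for v in vs:
                row = design_row(v.time_years, age_std[i], female[i],
                                 v.long_segment, v.esophagitis)
                for k, m in enumerate(MARKERS):
                    val = v.marker(m)
                    if not math.isnan(val):
                        X_obs[k].append(row)
                        y_obs[k].append(val)
                        pat_obs[k].append(i)

            # covariate intervals [t_j, t_{j+1}) clipped to [0, T_i]
            first_iv = len(iv_pat)
            for j, v in enumerate(vs):
                lo = starts[j]
                hi = starts[j + 1] if j + 1 < len(vs) else T[i]
                hi = min(hi, T[i])
                if lo >= T[i] and j > 0:
                    break
                iv_pat.append(i)
                iv_start.append(lo)
                iv_end.append(max(hi, lo))
                iv_x5.append([1.0, age_std[i], female[i],
                              v.long_segment, v.esophagitis])
            iv_ptr.append(len(iv_pat))

            my_starts = np.array(iv_start[first_iv:iv_ptr[-1]])
            my_x5 = iv_x5[first_iv:]

            def interval_of(t):
                return first_iv + int(
                    np.clip(np.searchsorted(my_starts, t, side="right") - 1,
                            0, len(my_starts) - 1)
                )

            # quadrature panels over [entry, T_i]
            inner = np.concatenate([
                knots[(knots > entry[i]) & (knots < T[i])],
                my_starts[(my_starts > entry[i]) & (my_starts < T[i])],
            ])
            breaks = np.unique(np.concatenate([[entry[i], T[i]], inner]))
            for a, b in zip(breaks[:-1], breaks[1:]):
                x, w = gauss_legendre_nodes(a, b, _GL)
                for t_q, w_q in zip(x, w):
                    m = interval_of(t_q)
                    node_t.append(t_q)
                    node_w.append(w_q)
                    node_pat.append(i)
                    node_seg.append(int(baseline.segment_index(t_q)))
                    node_iv.append(m)
                    x5 = iv_x5[m]
                    node_w4.append([x5[1], x5[2], x5[3], x5[4]])
            if delta[i] == 1:
                m = interval_of(T[i])
                ev_pat.append(i)
                ev_t.append(T[i])
                ev_seg.append(int(baseline.segment_index(T[i])))
                ev_iv.append(m)
                x5 = iv_x5[m]
                ev_w4.append([x5[1], x5[2], x5[3], x5[4]])

        return cls(
            n=n,
            patient_ids=list(ids),
            X_obs=[np.array(x, dtype=float).reshape(-1, N_FIXED) for x in X_obs],
            y_obs=[np.array(y, dtype=float) for y in y_obs],
            pat_obs=[np.array(p, dtype=int) for p in pat_obs],
            iv_ptr=np.array(iv_ptr, dtype=int),
            iv_pat=np.array(iv_pat, dtype=int),
            iv_start=np.array(iv_start, dtype=float),
            iv_end=np.array(iv_end, dtype=float),
            iv_x5=np.array(iv_x5, dtype=float).reshape(-1, 5),
            node_t=np.array(node_t, dtype=float),
            node_w=np.array(node_w, dtype=float),
            node_pat=np.array(node_pat, dtype=int),
            node_seg=np.array(node_seg, dtype=int),
            node_iv=np.array(node_iv, dtype=int),
            node_w4=np.array(node_w4, dtype=float).reshape(-1, 4),
            delta=delta,
            T=T,
            entry=entry,
            ev_pat=np.array(ev_pat, dtype=int),
            ev_t=np.array(ev_t, dtype=float),
            ev_seg=np.array(ev_seg, dtype=int),
            ev_iv=np.array(ev_iv, dtype=int),
            ev_w4=np.array(ev_w4, dtype=float).reshape(-1, 4),
            baseline_template=baseline,
        )

    # ------------------------------------------------------------------
    def marker_process(self, k: int, beta_k: np.ndarray, b_k: np.ndarray,
                       scale: str = "probability"):
        """Value and running-integral of marker k's process at quadrature
        nodes and event times, given fixed effects and intercepts b_k (n,)."""
        beta5 = beta_k[_BETA5_COLS]
        c = beta_k[1]
        a_iv = self.iv_x5 @ beta5 + b_k[self.iv_pat]

        if scale == "probability":
            full = expit_time_integral(a_iv, c, self.iv_start, self.iv_end)
        else:
            full = linear_time_integral(a_iv, c, self.iv_start, self.iv_end)
        cum = np.cumsum(full)
        base = cum - full  # integral from patient start up to interval start...
        # ...minus the global offset of the patient's first interval
        offset = base[self.iv_ptr[:-1]][self.iv_pat]
        I_start = base - offset

        def at(times, iv_idx):
            a = a_iv[iv_idx]
            if scale == "probability":
                val = special.expit(a + c * times)
                partial = expit_time_integral(a, c, self.iv_start[iv_idx], times)
            else:
                val = a + c * times
                partial = linear_time_integral(a, c, self.iv_start[iv_idx], times)
            return val, I_start[iv_idx] + partial

        v_node, I_node = at(self.node_t, self.node_iv)
        if len(self.ev_t):
            v_ev, I_ev = at(self.ev_t, self.ev_iv)
        else:
            v_ev = I_ev = np.zeros(0)
        return v_node, I_node, v_ev, I_ev

    def bernoulli_loglik(self, k: int, beta_k: np.ndarray, b_k: np.ndarray,
                         per_patient: bool = False):
        if len(self.y_obs[k]) == 0:
            return np.zeros(self.n) if per_patient else 0.0
        eta = self.X_obs[k] @ beta_k + b_k[self.pat_obs[k]]
        ll = _bern_loglik(eta, self.y_obs[k])
        if per_patient:
            return np.bincount(self.pat_obs[k], weights=ll, minlength=self.n)
        return float(ll.sum())

    def survival_loglik(
        self,
        log_rates: np.ndarray,
        gamma: np.ndarray,
        alpha_value: np.ndarray,
        alpha_cum: np.ndarray,
        marker_nodes,  # list of (v_node, I_node, v_ev, I_ev) per marker
        per_patient: bool = False,
    ):
        s_node = self.node_w4 @ gamma + log_rates[self.node_seg]
        s_ev = (self.ev_w4 @ gamma + log_rates[self.ev_seg]
                if len(self.ev_t) else np.zeros(0))
        for k in range(3):
            v_node, I_node, v_ev, I_ev = marker_nodes[k]
            s_node = s_node + alpha_value[k] * v_node + alpha_cum[k] * I_node
            if len(self.ev_t):
                s_ev = s_ev + alpha_value[k] * v_ev + alpha_cum[k] * I_ev
        H = np.bincount(self.node_pat, weights=self.node_w * np.exp(s_node),
                        minlength=self.n)
        ll = -H
        if len(self.ev_t):
            ll[self.ev_pat] += s_ev
        if per_patient:
            return ll
        return float(ll.sum())

    def loglik(self, long_params, surv: SurvivalParams, b: np.ndarray,
               per_patient: bool = False):
        """Data log-likelihood (Bernoulli + event terms) given intercepts b.

        Excludes the random-effects density; samplers add log N(b; 0, D)
        themselves.
        """
        beta = long_params.beta_matrix()
        scale = surv.association_scale
        marker_nodes = [
            self.marker_process(k, beta[k], b[:, k], scale) for k in range(3)
        ]
        ll_surv = self.survival_loglik(
            surv.baseline.log_rates, surv.gamma, surv.alpha_value,
            surv.alpha_cumulative, marker_nodes, per_patient=per_patient,
        )
        ll_bern = sum(
            self.bernoulli_loglik(k, beta[k], b[:, k], per_patient=per_patient)
            for k in range(3)
        )
        return ll_bern + ll_surv
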