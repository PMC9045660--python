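"""Hazard of neoplastic progression under the multivariate joint model.

The instantaneous hazard couples a piecewise-constant baseline with the
covariate effects and, per marker k, a *value* association on the current
modelled probability of aberrant expression pi_k(t) and an *accumulated
effect* association on its running integral:

    h(t) = exp( log lambda(t) + gamma' w(t)
                + sum_k [ a_value_k * pi_k(t)
                          + a_cum_k * int_0^t pi_k(s) ds ] )

Associations act on the probability scale by default (a 10% shift in the
probability of aberrant expression multiplies the hazard by exp(0.1 a)); a
logit-scale variant is available behind ``association_scale``.

Because time enters the marker linear predictors linearly and the remaining
covariates are step functions, the running integral of expit(a + c s) has
the closed form [softplus(a + c s)/c], which this module uses throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "BaselineHazard",
    "SurvivalParams",
    "expit_time_integral",
    "hazard_at",
    "cumulative_hazard",
    "gauss_legendre_nodes",
]

_GL_NODES = 15


_leggauss_cache: dict = {}


def gauss_legendre_nodes(t0, t1, n: int = _GL_NODES):
    """Nodes and weights of the n-point Gauss-Legendre rule on [t0, t1]."""
    if n not in _leggauss_cache:
        _leggauss_cache[n] = np.polynomial.legendre.leggauss(n)
    x, w = _leggauss_cache[n]
    mid, half = 0.5 * (t0 + t1), 0.5 * (t1 - t0)
    return mid + half * x, half * w


def expit_time_integral(a, c, t0, t1):
    """int_{t0}^{t1} expit(a + c*s) ds, elementwise.

    Equals (softplus(a + c t1) - softplus(a + c t0)) / c, with the c -> 0
    limit expit(a) * (t1 - t0).
    """
    a = np.asarray(a, dtype=float)
    if np.ndim(c) == 0:
        # common case: scalar time slope per marker
        if abs(float(c)) < 1e-10:
            out = special.expit(a) * (np.asarray(t1, dtype=float) - t0)
        else:
            out = (np.logaddexp(0.0, a + c * np.asarray(t1, dtype=float))
                   - np.logaddexp(0.0, a + c * np.asarray(t0, dtype=float))) / c
        return out if np.ndim(out) else float(out)
    c_arr = np.broadcast_to(np.asarray(c, dtype=float), a.shape)
    t0 = np.broadcast_to(np.asarray(t0, dtype=float), a.shape)
    t1 = np.broadcast_to(np.asarray(t1, dtype=float), a.shape)
    small = np.abs(c_arr) < 1e-10
    c_safe = np.where(small, 1.0, c_arr)
    sp1 = np.logaddexp(0.0, a + c_safe * t1)
    sp0 = np.logaddexp(0.0, a + c_safe * t0)
    out = np.where(small, special.expit(a) * (t1 - t0), (sp1 - sp0) / c_safe)
    return out if out.shape else float(out)


def linear_time_integral(a, c, t0, t1):
    """int_{t0}^{t1} (a + c*s) ds — logit-scale accumulated effect."""
    a = np.asarray(a, dtype=float)
    out = a * (np.asarray(t1) - np.asarray(t0)) + 0.5 * np.asarray(c) * (
        np.asarray(t1) ** 2 - np.asarray(t0) ** 2
    )
    return out if out.shape else float(out)


@dataclass
class BaselineHazard:
    """Piecewise-constant baseline hazard.

    ``knots`` are the K+1 increasing edges of the K constant pieces; the
    support is [knots[0], knots[-1]]. Evaluation outside the support raises.
    """

    knots: np.ndarray
    log_rates: np.ndarray

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        self.log_rates = np.asarray(self.log_rates, dtype=float)
        if self.log_rates.ndim != 1 or len(self.log_rates) < 1:
            raise ValueError("need at least one baseline-hazard interval")
        if len(self.knots) != len(self.log_rates) + 1:
            raise ValueError("knots must have len(log_rates)+1 edges")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")

    @property
    def n_intervals(self) -> int:
        return len(self.log_rates)

    def segment_index(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.knots[0] - 1e-12) or np.any(t > self.knots[-1] + 1e-12):
            raise ValueError(
                f"time outside baseline-hazard support "
                f"[{self.knots[0]}, {self.knots[-1]}]"
            )
        idx = np.clip(np.searchsorted(self.knots, t, side="right") - 1,
                      0, self.n_intervals - 1)
        return idx

    def log_rate_at(self, t):
        return self.log_rates[self.segment_index(t)]

    @classmethod
    def from_event_times(cls, event_times, n_intervals: int = 5,
                         t_start: float = 0.0, horizon: float | None = None,
                         init_rate: float | None = None) -> "BaselineHazard":
        """Knots at event-time quantiles; equal log-rates as initial values."""
        event_times = np.asarray(event_times, dtype=float)
        if horizon is None:
            horizon = float(event_times.max()) + 10.0 if len(event_times) else 20.0
        if len(event_times) >= n_intervals:
            qs = np.quantile(event_times, np.linspace(0, 1, n_intervals + 1)[1:-1])
            interior = np.unique(np.round(qs, 6))
            interior = interior[(interior > t_start) & (interior < horizon)]
        else:
            interior = np.array([])
        knots = np.concatenate([[t_start], interior, [horizon]])
        rate = init_rate if init_rate is not None else 1e-2
        return cls(knots=knots, log_rates=np.full(len(knots) - 1, math.log(rate)))


#: Survival covariates, in design order.
SURV_COVARIATE_NAMES = ("age_std", "female", "long_segment", "esophagitis")


@dataclass
class SurvivalParams:
    """Baseline hazard, covariate coefficients, and per-marker associations.

    ``alpha_value`` and ``alpha_cumulative`` are per unit probability and per
    unit probability-year respectively (length 3, marker order LGD, p53,
    SOX2); the field-standard report scale is the hazard ratio per 10%
    change, exp(0.1 * alpha).
    """

    baseline: BaselineHazard
    gamma: np.ndarray
    alpha_value: np.ndarray
    alpha_cumulative: np.ndarray
    association_scale: str = "probability"

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.alpha_value = np.asarray(self.alpha_value, dtype=float)
        self.alpha_cumulative = np.asarray(self.alpha_cumulative, dtype=float)
        if self.gamma.shape != (4,):
            raise ValueError("gamma must have 4 entries (age_std, female, "
                             "long_segment, esophagitis)")
        if self.alpha_value.shape != (3,) or self.alpha_cumulative.shape != (3,):
            raise ValueError("alpha_value/alpha_cumulative must have 3 entries")
        if self.association_scale not in ("probability", "logit"):
            raise ValueError("association_scale must be 'probability' or 'logit'")
        if not (np.all(np.isfinite(self.gamma))
                and np.all(np.isfinite(self.alpha_value))
                and np.all(np.isfinite(self.alpha_cumulative))):
            raise ValueError("survival parameters must be finite")


def hazard_at(t, params: SurvivalParams, pi, running_integrals, w) -> float:
    """Instantaneous hazard at time t.

    Parameters
    ----------
    pi, running_integrals
        Sequences of three callables s -> pi_k(s) and s -> int_0^s pi_k,
        on the association scale of ``params``.
    w
        Length-4 covariate vector (age_std, female, long_segment,
        esophagitis) at t.
    """
    log_h = float(params.baseline.log_rate_at(t)) + float(
        np.dot(params.gamma, np.asarray(w, dtype=float))
    )
    for k in range(3):
        log_h += params.alpha_value[k] * float(pi[k](t))
        log_h += params.alpha_cumulative[k] * float(running_integrals[k](t))
    return math.exp(log_h)


def cumulative_hazard(
    t0: float,
    t1: float,
    params: SurvivalParams,
    pi,
    running_integrals,
    w_of_t,
    extra_breaks=(),
    n_nodes: int = _GL_NODES,
) -> float:
    """Gauss-Legendre cumulative hazard over [t0, t1].

    The integral is split at every baseline-hazard knot (and any
    ``extra_breaks``, e.g. step-covariate change points) so each panel
    integrates a smooth function; ``n_nodes`` nodes per panel.
    """
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    knots = params.baseline.knots
    if t0 < knots[0] - 1e-12 or t1 > knots[-1] + 1e-12:
        raise ValueError("integration range outside baseline-hazard support")
    breaks = np.unique(np.concatenate([
        [t0, t1],
        knots[(knots > t0) & (knots < t1)],
        np.asarray([b for b in extra_breaks if t0 < b < t1], dtype=float),
    ]))
    total = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        x, wts = gauss_legendre_nodes(a, b, n_nodes)
        hs = np.array([
            hazard_at(t, params, pi, running_integrals, w_of_t(t)) for t in x
        ])
        total += float(wts @ hs)
    return total
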