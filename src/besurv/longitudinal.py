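"""Random-intercept logistic submodels for the three binary biomarkers.

Each marker k in {LGD, p53, SOX2} follows

    logit P(y_ij = 1 | b_ik) = x_ij' beta_k + b_ik,      b_ik ~ N(0, sigma_k^2)

with fixed-effect design x = (1, time, age_std, female, long_segment,
esophagitis). The standalone fitter maximizes the marginal likelihood with
the random intercept integrated out by adaptive Gauss-Hermite quadrature
(mode + curvature recentred per patient), and reports Wald 95% CIs and
odds ratios. Missing marker values contribute nothing to the likelihood;
patients with no non-missing observation contribute a factor of one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .cohort import MARKERS, Cohort, standardized_age

__all__ = [
    "COVARIATE_NAMES",
    "LongitudinalParams",
    "MarkerFit",
    "SeparationError",
    "linear_predictor",
    "marker_probability",
    "design_row",
    "fit_mixed_logistic",
    "odds_ratios",
    "marginal_loglik",
]

COVARIATE_NAMES = ("intercept", "time", "age_std", "female",
                   "long_segment", "esophagitis")
N_FIXED = len(COVARIATE_NAMES)


class SeparationError(RuntimeError):
    """Raised when a marker is degenerate or a covariate separates it."""


@dataclass
class LongitudinalParams:
    """Fixed effects per marker plus the 3x3 random-intercept covariance."""

    beta: dict[str, np.ndarray]  # marker -> length-6 fixed effects
    D: np.ndarray  # 3x3 covariance of (b_lgd, b_p53, b_sox2)

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        for k in MARKERS:
            self.beta[k] = np.asarray(self.beta[k], dtype=float)
            if self.beta[k].shape != (N_FIXED,):
                raise ValueError(f"beta[{k}] must have {N_FIXED} entries")
        if self.D.shape != (3, 3) or not np.allclose(self.D, self.D.T):
            raise ValueError("D must be a symmetric 3x3 matrix")
        if np.any(np.linalg.eigvalsh(self.D) <= 0):
            raise ValueError("D must be positive definite")

    def beta_matrix(self) -> np.ndarray:
        return np.stack([self.beta[k] for k in MARKERS])


def linear_predictor(beta: np.ndarray, covariates: np.ndarray, b: float) -> float:
    """eta = beta . x + b on the logit scale."""
    beta = np.asarray(beta, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if beta.shape[-1] != covariates.shape[-1]:
        raise ValueError(
            f"dimension mismatch: beta has {beta.shape[-1]} entries, "
            f"covariates {covariates.shape[-1]}"
        )
    return float(beta @ covariates + b)


def marker_probability(eta) -> np.ndarray | float:
    """expit(eta); strictly increasing in the random intercept, in (0,1)."""
    return special.expit(eta)


def design_row(time: float, age_std: float, female: int,
               long_segment: int, esophagitis: int) -> np.ndarray:
    return np.array([1.0, time, age_std, female, long_segment, esophagitis])


@dataclass
class MarkerFit:
    marker: str
    names: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    sigma_b: float
    sigma_b_se: float | None
    loglik: float
    converged: bool
    n_patients: int
    n_obs: int
    age_scaler: tuple[float, float] | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "marker": self.marker,
                "names": list(self.names),
                "estimates": self.estimates.tolist(),
                "se": self.se.tolist(),
                "ci_lower": self.ci_lower.tolist(),
                "ci_upper": self.ci_upper.tolist(),
                "sigma_b": self.sigma_b,
                "sigma_b_se": self.sigma_b_se,
                "loglik": self.loglik,
                "converged": self.converged,
                "n_patients": self.n_patients,
                "n_obs": self.n_obs,
                "age_scaler": list(self.age_scaler) if self.age_scaler else None,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MarkerFit":
        d = json.loads(text)
        return cls(
            marker=d["marker"],
            names=tuple(d["names"]),
            estimates=np.array(d["estimates"]),
            se=np.array(d["se"]),
            ci_lower=np.array(d["ci_lower"]),
            ci_upper=np.array(d["ci_upper"]),
            sigma_b=d["sigma_b"],
            sigma_b_se=d["sigma_b_se"],
            loglik=d["loglik"],
            converged=d["converged"],
            n_patients=d["n_patients"],
            n_obs=d["n_obs"],
            age_scaler=tuple(d["age_scaler"]) if d["age_scaler"] else None,
        )


def marker_design(cohort: Cohort, marker: str):
    """Flat (X, y, patient_index) arrays over non-missing observations."""
    if cohort.age_scaler is None:
        raise ValueError("cohort must be age-standardized before model fitting")
    idx = {pid: i for i, pid in enumerate(cohort.patient_ids)}
    age_std = {
        b.patient_id: standardized_age(cohort, b.age_years)
        for b in cohort.baselines
    }
    female = {b.patient_id: b.female for b in cohort.baselines}
    rows, ys, pats = [], [], []
    for v in cohort.visits:
        val = v.marker(marker)
        if math.isnan(val):
            continue
        rows.append(
            design_row(v.time_years, age_std[v.patient_id], female[v.patient_id],
                       v.long_segment, v.esophagitis)
        )
        ys.append(val)
        pats.append(idx[v.patient_id])
    X = np.array(rows, dtype=float).reshape(-1, N_FIXED)
    return X, np.array(ys, dtype=float), np.array(pats, dtype=int), cohort.n_patients


def _bern_loglik(eta, y):
    # y*eta - log(1 + exp(eta)), stable
    return y * eta - np.logaddexp(0.0, eta)


def marginal_loglik(
    X: np.ndarray,
    y: np.ndarray,
    pat: np.ndarray,
    n_patients: int,
    beta: np.ndarray,
    sigma: float,
    n_quad: int = 15,
    newton_iter: int = 25,
) -> float:
    """Marginal log-likelihood with b integrated out by adaptive Gauss-Hermite.

    Per patient the integrand is recentred at the conditional mode of b and
    rescaled by the local curvature before applying the n_quad-node rule.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    offset = X @ beta
    if sigma <= 0:
        eta = offset
        return float(_bern_loglik(eta, y).sum())

    # Newton mode-finding for b_i, vectorized over patients.
    b = np.zeros(n_patients)
    inv_var = 1.0 / sigma**2
    for _ in range(newton_iter):
        eta = offset + b[pat]
        p = special.expit(eta)
        grad = np.bincount(pat, weights=y - p, minlength=n_patients) - b * inv_var
        hess = np.bincount(pat, weights=p * (1 - p), minlength=n_patients) + inv_var
        step = grad / hess
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = offset + b[pat]
    p = special.expit(eta)
    hess = np.bincount(pat, weights=p * (1 - p), minlength=n_patients) + inv_var
    scale = 1.0 / np.sqrt(hess)  # (n_patients,)

    # b_q = b_hat + sqrt(2) * scale * x_q
    bq = b[:, None] + math.sqrt(2.0) * scale[:, None] * nodes[None, :]
    log_terms = np.empty((n_patients, n_quad))
    for q in range(n_quad):
        eta_q = offset + bq[pat, q]
        ll_obs = np.bincount(pat, weights=_bern_loglik(eta_q, y), minlength=n_patients)
        log_phi = -0.5 * bq[:, q] ** 2 * inv_var - 0.5 * math.log(2 * math.pi) - math.log(sigma)
        log_terms[:, q] = math.log(weights[q]) + nodes[q] ** 2 + ll_obs + log_phi
    log_int = special.logsumexp(log_terms, axis=1) + 0.5 * math.log(2.0) + np.log(scale)
    return float(log_int.sum())


def fit_mixed_logistic(
    cohort: Cohort,
    marker: str,
    n_quad: int = 15,
    sigma_fixed: float | None = None,
) -> MarkerFit:
    """Maximum-likelihood fit of one marker's random-intercept logistic model.

    Parameters
    ----------
    cohort
        Age-standardized, validated cohort.
    marker
        One of ``"lgd"``, ``"p53"``, ``"sox2"``.
    n_quad
        Adaptive Gauss-Hermite nodes (default 15).
    sigma_fixed
        If given, the random-intercept sd is held at this value (0 reduces
        to ordinary logistic regression) instead of being estimated.
    """
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}")
    X, y, pat, n_patients = marker_design(cohort, marker)
    n_with_obs = len(np.unique(pat))
    if n_with_obs < 2:
        raise ValueError("need >=2 patients with observations of the marker")
    if y.min() == y.max():
        raise SeparationError(
            f"marker {marker} is constant ({int(y[0])}) in all observations"
        )

    estimate_sigma = sigma_fixed is None

    def unpack(theta):
        beta = theta[:N_FIXED]
        sigma = math.exp(theta[N_FIXED]) if estimate_sigma else float(sigma_fixed)
        return beta, sigma

    def nll(theta):
        beta, sigma = unpack(theta)
        return -marginal_loglik(X, y, pat, n_patients, beta, sigma, n_quad)

    x0 = np.zeros(N_FIXED + (1 if estimate_sigma else 0))
    x0[0] = special.logit(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    if estimate_sigma:
        x0[-1] = 0.0  # log sigma = 0 -> sigma 1

    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"gtol": 1e-5, "maxiter": 500})
    theta = res.x
    # finite-difference gradients rarely hit BFGS's internal tolerance
    # exactly; a small gradient norm is the operative criterion
    grad_ok = bool(res.success or np.linalg.norm(res.jac) < 1e-3)
    beta_hat, sigma_hat = unpack(theta)

    if np.max(np.abs(beta_hat)) > 15.0:
        worst = COVARIATE_NAMES[int(np.argmax(np.abs(beta_hat)))]
        raise SeparationError(
            f"marker {marker}: estimate for {worst!r} diverged "
            f"(|beta| > 15), suggesting complete separation"
        )

    # Numerical Hessian of the negative log-likelihood (central differences).
    k = len(theta)
    H = np.zeros((k, k))
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = nll(theta + ei + ej)
            fpm = nll(theta + ei - ej)
            fmp = nll(theta - ei + ej)
            fmm = nll(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        have_se = np.all(np.isfinite(se_all))
    except np.linalg.LinAlgError:
        se_all = np.full(k, np.nan)
        have_se = False

    z = 1.959963984540054
    se = se_all[:N_FIXED]
    sigma_se = None
    if estimate_sigma and have_se:
        # delta method for sigma = exp(log sigma)
        sigma_se = float(se_all[N_FIXED] * sigma_hat)

    return MarkerFit(
        marker=marker,
        names=COVARIATE_NAMES,
        estimates=beta_hat.copy(),
        se=se,
        ci_lower=beta_hat - z * se,
        ci_upper=beta_hat + z * se,
        sigma_b=float(sigma_hat),
        sigma_b_se=sigma_se,
        loglik=float(-res.fun),
        converged=bool(grad_ok and have_se),
        n_patients=n_with_obs,
        n_obs=len(y),
        age_scaler=cohort.age_scaler,
    )


def odds_ratios(fit: MarkerFit, include_intercept: bool = False):
    """Exponentiate a fit into an OR table (estimate and Wald 95% CI)."""
    import pandas as pd

    rows = []
    for i, name in enumerate(fit.names):
        if name == "intercept" and not include_intercept:
            continue
        rows.append(
            {
                "covariate": name,
                "or": math.exp(fit.estimates[i]),
                "ci_lower": math.exp(fit.ci_lower[i]),
                "ci_upper": math.exp(fit.ci_upper[i]),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")
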