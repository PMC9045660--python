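# Methods

## Model

The package targets surveillance cohorts of Barrett's-esophagus patients
with repeated endoscopies. Three dichotomous biomarkers — LGD histology
(NDBE vs LGD, "indefinite for dysplasia" treated as missing), p53
immunohistochemistry (normal vs aberrant: overexpression or loss), and SOX2
(normal vs loss) — are modelled per patient i, marker k, visit j as

    y_ikj | b_ik ~ Bernoulli(expit(x_ij' beta_k + b_ik)),
    b_i ~ N(0, D),   D a 3x3 covariance,

with fixed effects x = (1, time since index endoscopy in years,
standardized age, female, long segment >=3 cm, esophagitis). Segment length
and esophagitis are step functions, carried forward between visits; time
enters linearly, so between visits the linear predictor is affine in t and
the marker probability is defined continuously.

The time-to-HGD/EAC hazard is

    h_i(t) = exp( log lambda(t) + gamma' w_i(t)
                  + sum_k [ a_k^val pi_ik(t) + a_k^cum I_ik(t) ] ),

where lambda(t) is piecewise constant, w = (age_std, female,
long_segment(t), esophagitis(t)), pi_ik(t) is the current modelled
probability of an aberrant call and I_ik(t) = int_0^t pi_ik(s) ds its
running integral. Follow-up before 0.5 years is excluded (six-month run-in
against prevalent neoplasia), implemented as left truncation: the event
likelihood is delta_i log h_i(T_i) - H_i(0.5, T_i), and person-years are
T_i - 0.5.

Design choices that were genuinely open:

* **Association scale.** The marker process enters the hazard on the
  probability scale (not logit), because the association is interpreted per
  10% change in the probability of aberrant expression; hazard ratios are
  reported as exp(0.1 a). A logit-scale variant sits behind
  `association_scale="logit"`.
* **Accumulated effect.** Defined as the integral of pi from the index
  endoscopy to t, coefficient per probability-year — the simplest
  cumulative functional of the history; reported per 10% x year.
* **Baseline hazard.** Piecewise constant with K=5 intervals by default
  (K=3 on desk-scale fits), knots at event-time quantiles, constant
  extension to a horizon 10 y past the last observed time so prediction
  windows stay inside the support.
* **Two-stage presentation.** `fit_mixed_logistic` estimates each marker
  separately (independent intercept variance, adaptive Gauss-Hermite ML,
  Wald CIs) for odds-ratio tables and sampler initialization; the full D is
  estimated only inside the joint model.

## Priors and sampler

N(0, 10^2) on all fixed effects, survival coefficients, associations and
baseline log-rates; half-t(3, 2.5) on the random-intercept sds; uniform
over valid correlation matrices for the correlation part of D
(parameterized by atanh-correlations with the tanh Jacobian and a
positive-definiteness rejection).

Posterior exploration is Metropolis-within-Gibbs with blocks for each
beta_k, (gamma), per-marker (a^val, a^cum), log-rates, a joint
survival-parameter block over (gamma, a^val, a^cum, log-rates), vectorized
per-patient b_i proposals, and (log sd, atanh corr) for D. All blocks adapt
during burn-in only: a scalar step size chases ~25% acceptance and, once
enough history exists, the proposal covariance switches to the empirical
covariance of visited states (Haario-style); both freeze at the end of
burn-in. The joint survival block exists because the accumulated
associations trade off strongly against the baseline hazard's time shape
(an accumulated effect with roughly constant pi is close to a log-linear
time trend); without it split R-hat on those coordinates stalls near 2 at
desk scale. Defaults: 2 chains x 6000 iterations (1000 burn-in); chain c is
seeded with seed + c and identical configs give byte-identical draws. Any
scalar with split R-hat > 1.1 flags the fit `converged=False`; the result
is returned, never discarded.

Numerical kernels: marker running integrals use the closed form
int expit(a + c s) ds = [softplus(a + c s)]/c (with the c -> 0 limit), so
cumulative hazards need quadrature only over the hazard itself — 15-point
Gauss-Legendre per panel, panels split at baseline knots and covariate
change points. The separate-marker fitter integrates b by 15-node adaptive
Gauss-Hermite recentred at each patient's conditional mode. Patients with
no non-missing observation of a marker contribute a likelihood factor of
one; a constant observed marker raises a separation error, as does any
fixed effect diverging past |beta| > 15.

## Dynamic prediction

For a new patient with history H_t up to landmark t, each posterior draw
theta_j yields one intercept draw from

    p(b | H_t, T > t, theta_j) ∝ Bernoulli terms x exp(-H(0.5, t | b)) x N(b; 0, D_j)

via a 200-step Metropolis chain (proposal 0.6 chol(D_j)), initialized at
the empirical-Bayes mode of the Bernoulli + prior part under the
posterior-mean parameters. The window risk per draw is
1 - exp(-H_j(t, t + dt)) with covariates carried forward from the last
visit; the reported risk is the posterior mean with 2.5/97.5-percentile
interval (clamped into the interval in the rare heavy-tail case). An empty
history at t = 0 short-circuits to exact N(0, D_j) draws.

## Validation

Cases at landmark t are events in (t, t+horizon]; controls are under
observation and event-free at t+horizon; the AUC is the tie-half-credit
pairwise concordance of predicted window risks. Subjects censored inside
the window are excluded by default ("exclude"); an IPCW variant weights
pairs by inverse Kaplan-Meier censoring survival. Optimism correction is
Harrell's bootstrap: patients (clusters, never visits) are resampled,
the full pipeline refits per replicate, and corrected = apparent - mean
(AUC boot-on-boot - AUC boot-on-original); failed refits are dropped and
counted. The static comparator is a Cox model with delayed entry, Efron
ties (lifelines), baseline marker status (missing treated as normal, with a
count reported) and step-function segment length/esophagitis; its AUC
ranking uses the baseline linear predictor. Small cohorts under the
outcome-dependent staining design can quasi-separate on the sparse baseline
markers; a light ridge (penalizer 0.1) is applied only if the unpenalized
fit fails, and is recorded on the fit object.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: 631
patients by default, ages ~N(60, 11) clipped to (25, 95), 27% female, 76%
long-segment, 10% esophagitis per visit (redrawn each visit; segment length
fixed at baseline), visits every 1.5 y with truncated N(0, 0.15) jitter
from the index endoscopy, administrative closure at 12 y plus exponential
dropout with rate ln2/6.8 per year so the median follow-up is ~6.8 y.
Fixed effects mirror the order of magnitude of the reported longitudinal
models (e.g. per-year odds ratio 1.17 for p53 in time, age OR 1.58 for
LGD); value associations correspond to per-10% hazard ratios 1.02/1.26/1.43
for LGD/p53/SOX2 and small positive accumulated effects; these are
illustrative choices, not estimates. The constant baseline hazard
0.001/y was set once by pilot simulation so ~8.6% of included patients
progress, then frozen. Event times are drawn by inversion: H(0, t) =
-log u solved by bracketed Brent root-finding on the quadrature cumulative
hazard (closed-form marker integrals), giving exact piecewise-exponential
samples in the null case. The outcome-dependent immunohistochemistry
design — p53/SOX2 kept at every endoscopy of progressors but at one
uniformly chosen endoscopy of non-progressors, LGD never removed — is
applied by a separate operation so both complete and study-design data are
available with the same ground truth.

What the generator does **not** emulate: biopsy-level sampling error,
interobserver disagreement, regression/progression of the underlying
dysplasia state beyond the Bernoulli model, visit scheduling that reacts to
findings, or centre effects. Passing tests therefore show correctness of
the machinery under the model's own assumptions, not robustness to the
ways real surveillance data violate them. One consequence worth naming: in
the simulated study design the mere availability of a baseline p53/SOX2
call is strongly outcome-dependent (progressors are stained at every
endoscopy), which at desk scale hands a baseline-covariate Cox model an
artificially perfect AUC; the dynamic-vs-static comparison is therefore run
on complete-measurement cohorts, where it isolates the value of
longitudinal histories.

## Problem sizes and calibration checks

The shipped suite uses desk-scale versions of each experiment, chosen once:
parameter recovery runs 3 replicate cohorts of 150 patients (~13 events
each) under the study staining design with 2x1500 MCMC iterations, checking
that value-association posteriors are calibrated (truth within 4 posterior
sds) and that 95% credible intervals cover the generating values in at
least 16 of 18 pooled checks (value associations + marker time trends).
Accumulated-effect coefficients are excluded from that pool: with ~13
events they are only weakly identified against the baseline hazard's time
shape (at 600 patients / ~50 events all association posteriors cover their
generating values). Note that even at that size the posterior sd of a value
association is ~2, so recovery is assessed by calibration, not by a fixed
absolute error. The AUC comparison uses 250 patients, landmarks 1-3 with a
3-year window, 3 bootstrap replicates with shortened refits (1 chain x 900)
and reduced prediction draws (30 outer x 50 inner) — ranks, which are all
the AUC uses, stabilize far earlier than the risks themselves. Oracle
equivalence tolerances: 1e-6 absolute on the mixed-logistic marginal
log-likelihood vs adaptive quadrature, exact pairwise enumeration for the
window AUC, 1e-6 relative on cumulative hazards vs dense per-segment
trapezoids, and +-0.02 on the one-marker posterior-intercept mean vs a
2001-point grid.

## Known limitations

* Accumulated-effect associations and the baseline hazard are jointly
  weakly identified at small event counts; report both only with ~50+
  events.
* The observation-process likelihood ignores the staining-design indicator;
  this is ignorable for likelihood inference because selection depends only
  on observed outcome status, but no sensitivity analysis is provided.
* No competing risks, no interval censoring (the event time is the
  detection endoscopy time), no cure fraction, no centre effects.
* The random-intercept prior is not tilted by survival through the run-in;
  with hazards of order 1e-3/y over 0.5 y the selection effect is
  negligible.
* Clinical surveillance intervals (3-year/1-year/eradication-therapy
  thresholds) are deliberately out of scope; the package stops at risks.
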