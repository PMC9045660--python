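# besurv

Dynamic, individualized risk estimation for Barrett's-esophagus (BE)
surveillance.

Patients with BE undergo periodic endoscopy to catch progression to
high-grade dysplasia or esophageal adenocarcinoma (HGD/EAC) early. Standard
practice grades risk from the **most recent** biopsy only, even though
histology (low-grade dysplasia, LGD) and immunohistochemical markers (p53,
SOX2) fluctuate between endoscopies. `besurv` implements the alternative:
model each patient's whole longitudinal marker history and convert it into a
progression risk that updates at every visit. It is aimed at biostatisticians
and modellers working on surveillance-interval personalization.

## Model

Three dichotomous biomarkers k ∈ {LGD, p53, SOX2} follow random-intercept
logistic models

  logit P(y_ikj = 1 | b_ik) = x_ij'β_k + b_ik,  b_i = (b_i1,b_i2,b_i3)' ~ N(0, D),

with x = (1, time, standardized age, gender, BE length ≥3 cm, esophagitis).
The HGD/EAC hazard couples to the three marker processes through their
current value π_ik(t) = expit(η_ik(t)) and accumulated history:

  h_i(t) = exp( log λ(t) + γ'w_i(t) + Σ_k [ α_k^val π_ik(t) + α_k^cum ∫₀ᵗ π_ik(s) ds ] ),

with a piecewise-constant baseline λ(t) and delayed entry at 0.5 y (a
six-month run-in excludes prevalent neoplasia). Fitting is Bayesian
(adaptive Metropolis-within-Gibbs); associations are reported as hazard
ratios per 10% change, HR = exp(0.1 α). Individualized prediction draws a
new patient's b from p(b | history, T > t, θ) per posterior draw and
averages the window risk 1 − exp(−H(t, t+Δt)). Validation computes landmark
window AUCs (years 1–6, 3-year horizon) with Harrell bootstrap optimism
correction against a static baseline-covariate Cox comparator. A synthetic
cohort generator with known ground truth makes every stage testable.

## Worked example

`examples/01_simulate_cohort.py` generates a study-scale cohort (631
patients) and prints:

```
eligible patients:        631
excluded (<6 mo FU):      30
excluded (no marker data):   0
included:                 601

events (HGD/EAC): 54 (9.0%)
median follow-up: 6.7 years
incidence: 1.4 per 100 person-years (95% CI 1.1-1.8) over 3809 PY
```

i.e. ~9% of included patients progress, at an incidence of 1.4 per 100
person-years of post-run-in follow-up. `examples/04_dynamic_prediction.py`
then fits the joint model and tracks one patient who accumulates aberrant
calls (p53 at year 1.2; LGD, p53 and SOX2 loss at year 2.5):

```
3-year progression risk at successive landmarks:
  year 1:   0.4% (95% CrI 0.0-4.7%)
  year 2:   2.5% (95% CrI 0.0-14.6%)
  year 3:   7.6% (95% CrI 0.0-62.5%)
  year 4:  10.4% (95% CrI 0.1-73.6%)
```

The 3-year risk climbs ~25-fold as aberrant measurements accrue — the
dynamic updating that fixed-interval surveillance ignores. The remaining
examples cover the per-marker odds-ratio tables (`02`), the hazard-ratio
table on the per-10% scale (`03`), and the dynamic-vs-static AUC comparison
(`05`). A thin CLI (`besurv simulate|fit|predict|validate --config
cfg.yaml`) wires the same stages to the shell with YAML configs and
provenance files.

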