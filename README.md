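# tgios

Tumor-growth-inhibition (TGI) metrics and TGI-driven overall-survival (OS)
modeling and trial simulation for maintenance treatment in non-small cell
lung cancer (NSCLC).

## The problem

In NSCLC, patients whose disease does not progress during first-line
chemotherapy may be randomized to *maintenance* treatment. Whether a
maintenance regimen will eventually prolong overall survival is unknown at
the time progression-free-survival data mature, yet that is when
development decisions are made. This package implements a two-stage
modeling framework that addresses exactly that gap for pharmacometricians
and biostatisticians:

1. **Longitudinal tumor-size model.** The sum of longest diameters TS(t)
   follows exponential growth at rate KL opposed by an exponentially
   waning drug effect in each phase (KDE1, λ1 during first line; KDE2, λ2
   during maintenance from randomization time t₁):

       TS(t) = BASE·exp( KL·t − (KDE1/λ1)(1 − e^(−λ1·t)) ),       t ≤ t₁
       TS(t) = TS(t₁)·exp( KL·u − (KDE2/λ2)(1 − e^(−λ2·u)) ),     u = t − t₁

   fitted as a nonlinear mixed-effects model (Laplace approximation,
   lognormal random effects). Per patient, two maintenance-phase metrics
   follow in closed form: the **time to tumor regrowth**
   TTG = ln(KDE2/KL)/λ2 (negative when the tumor regrows immediately) and
   the **week-8 early change in tumor size** ECTS = TS(t₁+8)/TS(t₁).

2. **Parametric OS model.** Survival is regressed on TTG and baseline
   prognostic factors with an accelerated-failure-time model,
   log T = Xβ + s·ε; the error family is chosen among six candidates by
   AIC (lognormal wins on this class of data) and covariates are screened
   by univariate Cox regression (p < 0.05) then backward-eliminated by
   likelihood-ratio tests (p < 0.01).

3. **Trial simulation.** The fitted OS model, with coefficients sampled
   from their uncertainty distribution per replicate, simulates trials
   patient-by-patient (Kaplan-Meier per arm, unadjusted Cox hazard ratio)
   to give posterior predictive checks and 95 % prediction intervals for
   the HR and median OS of an ongoing or planned study.

No patient-level data from the source trials are available, so the
`synthetic_data` module generates complete studies — sparse RECIST-style
tumor series with progression-linked dropout, covariate tables with
study-specific frequencies, and survival records — from the published
population parameters; every stage is validated against those.

## Worked example

```python
import numpy as np
from tgios import (REFERENCE_TGI_MODEL, compute_ttg, compute_ects8,
                   filter_evaluable, fit_population, fit_aft,
                   simulate_trial, CensoringSpec)
from tgios.synthetic_data import make_fixture, sample_os_cohort

typ = REFERENCE_TGI_MODEL.typical
print(f"typical TTG  : {compute_ttg(typ):.2f} weeks")
print(f"typical ECTS8: {compute_ects8(typ, 12.0):.3f}")

# fit the population model to a synthetic 150-patient study
from tgios import EstimationSettings
study = make_fixture("saturn_like", np.random.default_rng(42), n_patients=150)
fit = fit_population(filter_evaluable(study.tumor), REFERENCE_TGI_MODEL,
                     EstimationSettings(compute_se=False))
print(f"recovered KL : {fit.population.typical.KL:.5f} per week")

# OS regression and a prospective two-arm simulation
cohort = sample_os_cohort(253, np.random.default_rng(7), two_arm=True)
os_model = fit_aft(cohort, ["TTG_WK", "BTS_CM", "AGE_GE55", "ASIAN",
                            "ECOG_GT0", "FEMALE"])
summary = simulate_trial(
    os_model, cohort, n_rep=2000,
    censoring=CensoringSpec("uniform_duration", duration_bounds=(50, 140)),
    rng=np.random.default_rng(1), treatment_label="treatment")
print(f"HR median {summary.hr_median:.2f}, "
      f"95% PI ({summary.hr_pi95[0]:.2f}, {summary.hr_pi95[1]:.2f})")
```

prints (seeds as above):

```
typical TTG  : -1.99 weeks
typical ECTS8: 1.011
recovered KL : 0.00318 per week
HR median 0.87, 95% PI (0.69, 1.09)
```

The typical patient's profile regrows ~2 weeks *before* randomization
(KL > KDE2 at the typical values) and is predicted to grow ~1.1 % over
the first 8 maintenance weeks. The population fit lands on the generating
growth rate's order (0.00464/week) — a single pooled two-arm study of 150
patients carries substantial Monte-Carlo error on KL, which the
multi-seed validation suite quantifies. The simulated two-arm maintenance
study — whose treatment arm shifts the TTG distribution by about +12
weeks — shows a favorable but non-significant hazard ratio whose
prediction interval still straddles 1 at n = 253, the realistic readout
for a study of that size.

More narrative walkthroughs live in `examples/` (one script per
capability). A thin CLI mirrors the pipeline stages:
`tgios generate | fit-tgi | fit-os | ppc | simulate-trial | run-all`.

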