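# Methods

## Scope

`tgios` implements a two-stage tumor-growth-inhibition → overall-survival
(TGI–OS) modeling framework for maintenance treatment in non-small cell
lung cancer: (1) a longitudinal model of tumor size (sum of longest
diameters, SLD) over a first-line run-in and a maintenance phase, fitted as
a nonlinear mixed-effects model, from which per-patient maintenance-phase
metrics are derived; (2) a parametric survival regression linking those
metrics and baseline prognostic factors to overall survival; and (3) a
trial-simulation engine that propagates survival-model parameter
uncertainty into prediction intervals for trial-level statistics (hazard
ratio, median OS per arm). Because no patient-level data from the source
trials are distributable, a synthetic-data module generates complete
studies with the same statistical structure; every pipeline stage is
exercised and validated on those.

## Tumor-size model

Tumor size follows exponential growth at rate `KL` (week⁻¹, shared by both
phases) opposed by a drug-effect kill rate that decays exponentially from
its initial value — `KDE1`, decaying at `LAMBDA1`, from the start of first
line, and `KDE2`, decaying at `LAMBDA2`, from the randomization time `t1`:

    dTS/dt = (KL − KDE(t)) · TS,
    KDE(t) = KDE1·exp(−λ1·t)            for 0 ≤ t ≤ t1
           = KDE2·exp(−λ2·(t − t1))     for t > t1

This ODE has a closed-form solution (implemented directly; an ODE
integrator appears only as a test oracle):

    TS(t)  = BASE · exp( KL·t − (KDE1/λ1)(1 − e^{−λ1 t}) ),  t ≤ t1
    TS(t)  = TS(t1) · exp( KL·u − (KDE2/λ2)(1 − e^{−λ2 u}) ), u = t − t1

The profile is continuous at `t1` by construction. Two maintenance-phase
metrics summarize it per patient:

* **TTG** (time to tumor regrowth) — the stationary point of the phase-2
  profile, `ln(KDE2/KL)/λ2` weeks after randomization. Negative exactly
  when `KL > KDE2` (the tumor regrows immediately); negative values are
  reported as such, never clipped.
* **Week-8 ECTS** (early change in tumor size) — `TS(t1+8)/TS(t1)`. The
  denominator is the model-predicted size at randomization, not the
  first-line baseline: only the maintenance-phase change is of interest,
  and with this convention the ratio depends on maintenance parameters
  only. An alternative reading (denominator `BASE` at t = 0, or week 8 on
  study) exists; the convention here is a documented choice, not a claim
  about the source analyses.

Default population parameters (`REFERENCE_TGI_MODEL`) are the published
estimates for this model class in the maintenance setting: typical values
KL 0.00464, KDE1 0.0566, λ1 0.117, KDE2 0.00412, λ2 0.0597 week⁻¹, BASE
7.74 cm; lognormal inter-individual SDs 1.05, 0.699, 0 (fixed), 1.64,
0.787, 0.64; additive residual SD √0.58 ≈ 0.76 cm. IIV on λ1 is fixed to
zero — it is not identifiable from the sparse run-in sampling. The residual
error is additive on the cm scale (its published variance is in cm²), and
simulated sizes are truncated at zero.

## Population estimation

The marginal likelihood integrates lognormal random effects η on (KL,
KDE1, KDE2, λ2, BASE) out of the Gaussian data likelihood. The integral is
approximated by Laplace's method:

* **Inner problem** — per patient, minimize the joint negative log density
  over η (penalized least squares in log-parameter space). Solved by a
  damped Gauss-Newton iteration with analytic Jacobians, vectorized across
  all patients simultaneously.
* **Curvature** — the Hessian at the mode uses the exact Gauss-Newton +
  second-order term (finite differences of the analytic Jacobian), falling
  back to the PSD Gauss-Newton curvature if a line-search point is
  indefinite.
* **Outer problem** — L-BFGS-B over (log typicals, log ωs, log σ), with
  inner modes warm-started between evaluations. Convergence is reported,
  never silently assumed; standard errors come from a central-difference
  Hessian of the outer objective (for log-parameterized quantities the SE
  of the log is the relative SE).

The approximation is validated against adaptive quadrature of the random
effects on two-patient problems with two active random effects (agreement
to three significant digits of the log-likelihood). Empirical-Bayes
("posthoc") estimates are the inner modes; parameters with ω = 0 stay at
their typical values exactly. Shrinkage is `100·(1 − SD(η)/ω)` per
parameter and `100·(1 − SD(IWRES))` for the residual; values can be
slightly negative by sampling noise. On sparse maintenance sampling the
fitted shrinkage ordering reproduces the published pattern (λ2 by far the
highest, BASE the lowest).

Evaluability rule: ≥ 1 measurement after randomization plus ≥ 1 at/before
it (the latter anchors BASE). Initialization defaults to the reference
typicals; tests perturb them by up to ±50 %.

## Overall-survival model

Screening uses univariate Cox proportional-hazards fits (Efron ties, via
lifelines) with the likelihood-ratio χ² as the score; hazard ratios are
reported per conventional units (8 weeks of TTG, 2 cm of baseline size,
10 % of size ratio, 10 years of age) while model coefficients stay on raw
scales. The OS regression itself is an accelerated-failure-time
location-scale model, `y = Xβ + s·ε` with `y = log T` (lognormal, Weibull,
log-logistic, exponential) or `y = T` (normal, logistic); right-censored
MLE by BFGS with observed-information covariance. Log-time families
include the 1/t Jacobian so AIC is comparable across all six families.
`select_family` ranks the six by AIC; `backward_eliminate` drops the
least-significant covariate (largest removal p, deterministic tie order)
while its 1-df LR test exceeds p = 0.01, re-testing all survivors after
each removal. The intercept is always retained.

The reference fitted model (`REFERENCE_OS_MODEL`, lognormal, time in
weeks) is: intercept 4.3776, TTG +0.0139/week, BTS −0.0437/cm, age ≥ 55
−0.2519, Asian +0.2324, ECOG > 0 −0.157, female +0.1437, log-scale
−0.3017. Its parameter covariance is taken diagonal in the published
standard errors — coefficient correlations were not reported; prediction
intervals that sample from it are therefore approximate in the
off-diagonal structure. Median survival is closed-form (`exp(Xβ)` for the
lognormal). Weeks are the internal unit everywhere; months are derived as
weeks × 7/30.4375 for reporting only.

## Trial simulation

Each replicate: draw (β, log s) from the multivariate normal uncertainty
distribution; draw one survival time per patient at their fixed covariates
(TTG held at its estimated/interim value); censor; analyze like a trial
(Kaplan-Meier per arm, unadjusted two-arm Cox for the HR). Statistics are
summarized by median and 2.5/97.5 percentiles across replicates
(percentile, not normal-approximation, intervals). Two censoring
mechanisms:

* `uniform_duration` — patient study duration ~ U(low, high) weeks
  (default 50–140), death beyond it censored;
* `fraction` — a single administrative cutoff solved numerically so the
  expected censored proportion matches a target (default 30 %), used for
  posterior predictive checks.

The replicate engine uses a dedicated one-parameter Efron-ties Cox Newton
solver and a vectorized product-limit estimator (both equivalence-tested
against lifelines) because ~10⁵ two-arm fits per calibration study would
be prohibitive through a general fitter. Arm labels are ordered
deterministically (sorted; explicit `treatment_label` override), so the HR
direction never depends on row order. Replicate HRs are unadjusted for
covariates, matching primary-analysis practice. Under a fixed seed the
full summary is reproducible bit for bit.

Calibration: the 95 % HR prediction interval is checked against the HR
realized by an independent replicate of the same trial under the
generating model — the quantity a prediction interval is designed to
cover. Against a fixed large-sample estimand instead, the interval is
conservative (it also carries single-trial sampling noise), and against a
covariate-marginal estimand it undercovers by design, since patient
covariates are deliberately held fixed.

## Synthetic data

`generate_study` emulates the structure of the three maintenance trials
the framework targets. Per patient: prognostic flags from study-specific
frequencies (published per-study values for female, ECOG > 0, age ≥ 55,
Asian); randomization at ~12 weeks (four 3-week first-line cycles) ± 1.5
weeks of assessment jitter; individual TGI parameters lognormal around the
typicals; 6-weekly assessments from first-line start to 48 weeks past
randomization. Follow-up is truncated by two mechanisms: a progression
proxy (first scan whose predicted size exceeds 1.2× the post-randomization
predicted nadir — that scan is kept, as the progression-documenting scan
is in real datasets) and an independent exponential dropout with median 16
weeks after randomization (death, toxicity, withdrawal). The progression
proxy alone leaves a median last observation ≈ 43 weeks post-randomization
under the reference parameters — far longer than the 11–18 weeks typical
of this setting — so the explicit dropout process is required; together
they give ≈ 11 weeks. A configurable fraction (default 94 %) of patients
is evaluable; the rest have their post-randomization scans withheld.

Treatment arms differ by a multiplier (default 2.0) on the typical KDE2,
shifting the TTG distribution by ≈ ln 2/λ2 ≈ 11.6 weeks — through the TTG
coefficient of the OS model this yields a SATURN-scale log-HR of about
−0.24. The typical BASE is recalibrated so the predicted size at
randomization matches the study's published median BTS, keeping the
trajectory, the BTS covariate and the OS model internally consistent (BTS
is read off the generated trajectory at t1, never drawn separately).
Survival times come from the OS model at the true TTG and covariates, with
uniform 50–140-week study-duration censoring (≈ 30 % censored under the
reference parameters).

What the generator does not emulate: EGFR subgroups, treatment switching,
inter-occasion variability, measurement-error correlation within patient,
informative censoring, or the real trials' exact assessment calendars.
Passing tests therefore demonstrate correctness of the estimation and
simulation machinery under the stated generating mechanisms, not clinical
reproduction of the source trials; the observed clinical HRs and medians
are out of reach without the patient-level data, by construction.

## Numerical choices and problem sizes

* Inner Gauss-Newton: ≤ 60 iterations, gradient tolerance 1e-9, adaptive
  damping; log-parameters clipped to ±25 during line searches.
* Outer L-BFGS-B: ftol 1e-9, gtol 1e-5, FD step 1e-5; ω bounded in
  [1e-3, 5], σ ≥ 1e-3.
* AFT fits: BFGS, gtol 1e-7; extreme-value exponent clamped at 600 to keep
  far-field line searches finite; rank-deficient designs rejected with the
  offending columns named.
* Degenerate inputs: all-censored KM warns and returns an undefined
  median; monotone-likelihood Cox fits return a flagged result rather than
  raising.
* Validation studies run at desk scale: population-fit recovery uses 5
  replicate studies of 250 patients (≈ 25 s per fit), OS-coefficient
  recovery 20 × 800 records, family selection 50 × 1500, elimination
  30 × 1500, PI calibration 200 truths × 500 replicates, PPC 1000
  replicates. Recovery checks use 3 Monte-Carlo-SE bands computed from the
  replicate spread at these sizes.

## Known limitations

* The Laplace approximation, like all first-order conditional estimation
  schemes, is biased on very sparse designs; with ~2–3 maintenance scans
  per patient, λ2 is weakly identified (shrinkage ≈ 80 %), and its typical
  value carries the largest recovery error.
* The diagonal OS-model covariance ignores coefficient correlations.
* The fraction-mode censoring cutoff is solved under the sampled model per
  replicate; with heavy-tailed parameter draws the realized censored
  fraction varies around the target.
* The week-8 ECTS convention (anchored at randomization) is one of two
  defensible readings; results that depend on its absolute scale should
  state the convention.
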