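"""Posterior predictive check and prospective trial simulation.

Simulates a 253-patient two-arm maintenance study (treatment shifts the
TTG distribution), checks the fitted model against its own data, and
produces the prospective HR prediction interval with parameter
uncertainty.
"""

import numpy as np

from tgios import CensoringSpec, fit_aft, run_ppc, simulate_trial
from tgios.synthetic_data import sample_os_cohort

FINAL_COVS = ["TTG_WK", "BTS_CM", "AGE_GE55", "ASIAN", "ECOG_GT0", "FEMALE"]

cohort = sample_os_cohort(253, np.random.default_rng(3), two_arm=True,
                          covariate_freqs={"FEMALE": 0.43, "ECOG_GT0": 0.52,
                                           "AGE_GE55": 0.72, "ASIAN": 0.12})
model = fit_aft(cohort, FINAL_COVS)
print(f"fitted lognormal AFT on {model.n} patients "
      f"({model.n_events} events), AIC {model.aic:.1f}")

# replicate the observed censoring mechanism (uniform study duration) so
# the band is comparable to the observed curve over the whole grid
ppc = run_ppc(model, cohort, n_rep=1000,
              censoring=CensoringSpec("uniform_duration",
                                      duration_bounds=(50, 140)),
              rng=np.random.default_rng(4), treatment_label="treatment")
for arm in ppc.bands:
    mask = cohort["ARM"] == arm
    cov = ppc.observed_km_coverage(arm, cohort.loc[mask, "TIME_WK"],
                                   cohort.loc[mask, "EVENT"].astype(bool))
    print(f"PPC: observed KM of arm {arm!r} inside the 95% band at "
          f"{cov:.0%} of times")

summary = simulate_trial(
    model, cohort, n_rep=5000,
    censoring=CensoringSpec("uniform_duration", duration_bounds=(50, 140)),
    rng=np.random.default_rng(5), treatment_label="treatment")
print(f"\nprospective simulation ({summary.n_replicates} replicates):")
print(f"  HR median {summary.hr_median:.2f}, "
      f"95% PI ({summary.hr_pi95[0]:.2f}, {summary.hr_pi95[1]:.2f})")
for arm in summary.arm_labels:
    med, lo, hi = summary.median_os_months[arm]
    print(f"  median OS {arm:>9}: {med:.1f} months (95% PI {lo:.1f}-{hi:.1f})")
print(f"  event fraction {summary.event_fraction:.0%}, "
      f"probability of success {summary.prob_success:.2f}")

# At n = 253 the treatment effect (TTG shifted ~+12 weeks) yields a
# favorable HR whose 95 % prediction interval still straddles 1: the
# simulation says a significant OS readout is unlikely at this sample
# size, which is exactly the decision-support question the framework
# answers from interim tumor-size data.
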