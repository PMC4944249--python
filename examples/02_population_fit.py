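"""Population (mixed-effects) fit of the tumor model to a synthetic study.

Generates a single-arm study from the reference population parameters,
filters to evaluable patients, fits, and compares the recovered typical
values, IIV SDs and shrinkage with the generating values.
"""

import numpy as np

from tgios import (EstimationSettings, REFERENCE_TGI_MODEL, filter_evaluable,
                   fit_population)
from tgios.synthetic_data import StudySpec, generate_study
from tgios.tgi_model import PARAM_NAMES

spec = StudySpec(name="demo", n_patients=150, arms=(("all", 1.0, 1.0),),
                 bts_median_cm=6.99)
study = generate_study(spec, rng=np.random.default_rng(11))
dataset = filter_evaluable(study.tumor)
print(f"{len(dataset.series)}/{spec.n_patients} patients evaluable "
      "(>=1 scan after randomization, >=1 at/before it)")

fit = fit_population(dataset, REFERENCE_TGI_MODEL,
                     EstimationSettings(compute_se=False))
print(f"converged: {fit.convergence['converged']}, "
      f"log-likelihood {fit.log_likelihood:.1f}\n")

print(f"{'parameter':>9} {'estimate':>10} {'omega':>7} {'shrink%':>8}")
for name in PARAM_NAMES:
    est = getattr(fit.population.typical, name)
    om = fit.population.omega.get(name, 0.0)
    sh = fit.shrinkage.get(name)
    print(f"{name:>9} {est:>10.5f} {om:>7.3f} "
          f"{sh:>8.1f}" if sh is not None else
          f"{name:>9} {est:>10.5f} {om:>7.3f}    fixed")
print(f"residual SD: {fit.population.sigma:.3f} cm "
      f"(shrinkage {fit.shrinkage['residual']:.1f} %)")

# The typicals land near the generating values (KL 0.00464, KDE2 0.00412,
# lambda2 0.0597 ...) and the shrinkage ordering reflects the sparse
# maintenance sampling: the decay rate lambda2 is weakly identified per
# patient (high shrinkage) while BASE, anchored by the run-in scans, is
# estimated almost individually (low shrinkage).
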