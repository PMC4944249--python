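"""End-to-end pipeline run on generated data, via the orchestration layer.

Generates a compact study, chains evaluability filtering, the population
TGI fit with posthoc metrics, Cox screening, family selection and backward
elimination, and prints the artifact manifest.
"""

import json
import tempfile
from pathlib import Path

from tgios import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = PipelineConfig(
        seed=17,
        output_dir=str(Path(tmp) / "out"),
        generate_preset="saturn_like",
        generate_n=120,
        stages=["generate", "fit_tgi", "screen", "fit_os", "simulate_trial"],
        n_rep_trial=500,
        treatment_arm="erlotinib",
    )
    manifest = run_pipeline(cfg)

    print(f"status: {manifest['status']}")
    print("artifacts:")
    for path, sha in sorted(manifest["files"].items()):
        print(f"  {Path(path).name:<28} sha256 {sha[:12]}...")

    out = Path(cfg.output_dir)
    model = json.loads((out / "os_model.json").read_text())
    print(f"\nfinal OS model: {model['family']}, "
          f"covariates {list(model['coefficients'])[1:]}")
    sim = json.loads((out / "trial_simulation.json").read_text())
    print(f"simulated HR median {sim['hr_median']:.2f}, "
          f"95% PI ({sim['hr_pi95'][0]:.2f}, {sim['hr_pi95'][1]:.2f})")

# Rerunning with the same seed and config reproduces every artifact
# checksum; each stage draws from its own seed stream, so toggling one
# stage never changes another's output.  Note the honest two-stage
# behavior at this tiny study size: the OS stage uses the posthoc
# (empirical-Bayes) TTG estimates, whose shrinkage attenuates the
# TTG-survival association, so TTG can drop out of the final model at
# n = 120 where the source analyses pooled ~1500 patients.
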