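"""Synthetic maintenance-trial data generator.

Emulates the statistical structure of the NSCLC maintenance studies the
framework targets: patients enter a ~12-week first-line run-in (four
cycles), are randomized to maintenance if their disease has not progressed,
and are then assessed on a sparse RECIST-like schedule until a
progression-proxy dropout.  Per patient the generator

1. draws prognostic covariates (female, ECOG>0, age>=55, Asian, plus
   screening-only smoking/histology flags) from study-specific frequencies;
2. draws individual TGI parameters lognormally around the population
   typical values, applying the treatment-arm effect as a multiplier on the
   maintenance drug-effect rate KDE2 (shifting the TTG distribution);
3. simulates noisy tumor-size series on a 6-weekly assessment grid,
   truncated once the model-predicted size exceeds 1.2x its
   post-randomization nadir (progression proxy), and withholds all
   post-randomization scans from a (1 - evaluable_fraction) subset;
4. computes the true TTG and week-8 ECTS from the generating parameters;
5. draws an overall-survival time from the OS model at the true TTG and
   covariates, censored by a uniform 50-140-week study duration.

The typical baseline size is calibrated so the model-predicted size at
randomization matches the study's published median tumor size at
randomization (BTS), keeping trajectory and covariate internally
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .os_survival import REFERENCE_OS_MODEL, OSModel
from .tgi_fit import TGIDataset
from .tgi_model import (
    REFERENCE_TGI_MODEL,
    TGIIndividualParams,
    TGIPopulationModel,
    TumorSeries,
    compute_ects8,
    compute_ttg,
    predict_size,
)

#: Nadir-relative predicted-size threshold used as the progression proxy.
PROGRESSION_RATIO = 1.2


@dataclass(frozen=True)
class StudySpec:
    """Design of one synthetic maintenance study.

    ``arms`` is a list of (label, allocation fraction, KDE2 multiplier);
    the multiplier scales the typical maintenance drug-effect rate for that
    arm (1.0 = control).  ``covariate_freqs`` holds Bernoulli probabilities
    for FEMALE, ECOG_GT0, AGE_GE55, ASIAN (and optionally NEVER_SMOKED,
    SQUAMOUS).  ``bts_median_cm`` is the target median tumor size at
    randomization.
    """

    name: str
    n_patients: int
    arms: tuple = (("control", 0.5, 1.0), ("treatment", 0.5, 2.0))
    covariate_freqs: dict = field(default_factory=lambda: {
        "FEMALE": 0.35, "ECOG_GT0": 0.65, "AGE_GE55": 0.72, "ASIAN": 0.13,
        "NEVER_SMOKED": 0.20, "SQUAMOUS": 0.20})
    bts_median_cm: float = 6.5
    t1_weeks: float = 12.0
    t1_jitter_weeks: float = 1.5
    assessment_interval_weeks: float = 6.0
    horizon_weeks: float = 48.0          # post-randomization assessment span
    dropout_median_weeks: float = 16.0   # post-t1 non-progression dropout
    evaluable_fraction: float = 0.94

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        alloc = sum(a[1] for a in self.arms)
        if abs(alloc - 1.0) > 1e-9:
            raise ValueError(f"arm allocations must sum to 1, got {alloc}")
        for key, p in self.covariate_freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"covariate frequency {key}={p} outside [0,1]")
        if not 0.0 < self.evaluable_fraction <= 1.0:
            raise ValueError("evaluable_fraction must be in (0, 1]")


@dataclass
class SyntheticStudy:
    spec: StudySpec
    tumor: TGIDataset
    covariates: pd.DataFrame             # one row per patient
    true_params: dict                    # patient_id -> TGIIndividualParams
    true_metrics: pd.DataFrame           # ID, TTG_WK, ECTS8, BTS_CM
    survival: pd.DataFrame               # ID, ARM, TIME_WK, EVENT + covariates
    seed_info: dict = field(default_factory=dict)

    def truth_dict(self) -> dict:
        return {
            "spec": {"name": self.spec.name, "n_patients": self.spec.n_patients},
            "params": {pid: dict(zip(
                ("KL", "KDE1", "LAMBDA1", "KDE2", "LAMBDA2", "BASE"),
                p.as_array().tolist())) for pid, p in self.true_params.items()},
            "metrics": self.true_metrics.to_dict(orient="list"),
            "seed_info": self.seed_info,
        }


def _calibrated_base_typical(tgi: TGIPopulationModel, spec: StudySpec) -> float:
    """Typical BASE such that the typical predicted size at t1 equals the
    study's median BTS."""
    typ = tgi.typical
    factor = predict_size(typ, spec.t1_weeks, spec.t1_weeks) / typ.BASE
    return spec.bts_median_cm / factor


def generate_study(spec: StudySpec,
                   tgi: TGIPopulationModel = REFERENCE_TGI_MODEL,
                   os_model: OSModel = REFERENCE_OS_MODEL,
                   rng: np.random.Generator | None = None) -> SyntheticStudy:
    """Generate one complete synthetic study (tumor, covariates, survival)."""
    rng = rng if rng is not None else np.random.default_rng()
    n = spec.n_patients
    base_typ = _calibrated_base_typical(tgi, spec)
    typical = TGIIndividualParams.from_array(
        np.concatenate([tgi.typical.as_array()[:5], [base_typ]]))
    population = TGIPopulationModel(typical=typical, omega=dict(tgi.omega),
                                    sigma=tgi.sigma)

    labels = [a[0] for a in spec.arms]
    alloc = np.array([a[1] for a in spec.arms])
    kde2_mult = {a[0]: a[2] for a in spec.arms}
    arm = rng.choice(labels, size=n, p=alloc)

    cov_rows = []
    series = []
    params_by_id = {}
    metric_rows = []
    surv_rows = []
    for i in range(n):
        pid = f"{spec.name}-{i:04d}"
        flags = {k: int(rng.random() < p)
                 for k, p in spec.covariate_freqs.items()}
        age = float(rng.uniform(55, 80) if flags.get("AGE_GE55")
                    else rng.uniform(35, 55))
        t1 = float(spec.t1_weeks + rng.uniform(-spec.t1_jitter_weeks,
                                               spec.t1_jitter_weeks))
        p_ind = population.draw_individual(rng)
        p_ind = replace_kde2(p_ind, kde2_mult[arm[i]])
        params_by_id[pid] = p_ind

        times = _assessment_times(spec, t1)
        pred = predict_size(p_ind, times, t1)
        times = _truncate_at_progression(times, pred, t1)
        # non-progression dropout (death, toxicity, withdrawal): exponential
        # follow-up beyond randomization, median dropout_median_weeks; the
        # first post-randomization scan is always retained — evaluability is
        # governed by evaluable_fraction below, not by dropout
        if spec.dropout_median_weeks > 0:
            follow_up = rng.exponential(
                spec.dropout_median_weeks / np.log(2.0))
            post = times > t1
            keep = (times <= t1 + follow_up)
            if post.any():
                keep[np.argmax(post)] = True
            times = times[keep]
        evaluable = rng.random() < spec.evaluable_fraction
        if not evaluable:
            times = times[times <= t1]
        if times.size == 0:
            times = np.array([0.0])
        sizes = np.maximum(
            predict_size(p_ind, times, t1)
            + rng.normal(0.0, tgi.sigma, size=times.size), 0.0)
        series.append(TumorSeries(patient_id=pid, t1=t1, times=tuple(times),
                                  sizes=tuple(sizes)))

        ttg = compute_ttg(p_ind)
        ects8 = compute_ects8(p_ind, t1)
        bts = float(predict_size(p_ind, t1, t1))
        metric_rows.append({"ID": pid, "TTG_WK": ttg, "ECTS8": ects8,
                            "BTS_CM": bts})
        cov_rows.append({"ID": pid, "ARM": arm[i], "AGE_YR": age, **flags})

        surv_cov = {"TTG_WK": ttg, "BTS_CM": bts,
                    "AGE_GE55": flags.get("AGE_GE55", 0),
                    "ASIAN": flags.get("ASIAN", 0),
                    "ECOG_GT0": flags.get("ECOG_GT0", 0),
                    "FEMALE": flags.get("FEMALE", 0)}
        mu = float(os_model.linear_predictor(surv_cov)[0])
        t_death = float(np.exp(mu + os_model.scale * rng.standard_normal()))
        duration = float(rng.uniform(50.0, 140.0))
        event = t_death <= duration
        surv_rows.append({"ID": pid, "ARM": arm[i],
                          "TIME_WK": t_death if event else duration,
                          "EVENT": int(event), **surv_cov,
                          "ECTS8": ects8, "AGE_YR": age,
                          "NEVER_SMOKED": flags.get("NEVER_SMOKED", 0),
                          "SQUAMOUS": flags.get("SQUAMOUS", 0)})

    return SyntheticStudy(
        spec=spec,
        tumor=TGIDataset(series=series),
        covariates=pd.DataFrame(cov_rows),
        true_params=params_by_id,
        true_metrics=pd.DataFrame(metric_rows),
        survival=pd.DataFrame(surv_rows),
        seed_info={"generator": "generate_study", "study": spec.name},
    )


def replace_kde2(params: TGIIndividualParams, mult: float) -> TGIIndividualParams:
    if mult == 1.0:
        return params
    arr = params.as_array()
    arr[3] *= mult
    return TGIIndividualParams.from_array(arr)


def _assessment_times(spec: StudySpec, t1: float) -> np.ndarray:
    dt = spec.assessment_interval_weeks
    end = t1 + spec.horizon_weeks
    times = np.arange(0.0, end + 1e-9, dt)
    # randomization-day scan, as used to anchor the maintenance baseline
    if np.min(np.abs(times - t1)) > 1e-6:
        times = np.sort(np.append(times, t1))
    return times


def _truncate_at_progression(times: np.ndarray, pred: np.ndarray,
                             t1: float) -> np.ndarray:
    """Drop assessments after predicted progression (>= 1.2x post-t1 nadir).

    The progression-triggering assessment itself is retained, as the scan
    documenting progression is in the dataset in practice.
    """
    idx = np.where(times >= t1 - 1e-9)[0]   # maintenance-phase scans incl. t1
    if idx.size == 0:
        return times
    run_nadir = np.minimum.accumulate(pred[idx])
    prior_nadir = np.concatenate([[pred[idx][0]], run_nadir[:-1]])
    progressed = (pred[idx] >= PROGRESSION_RATIO * prior_nadir) \
        & (times[idx] > t1)
    if progressed.any():
        cut = idx[np.argmax(progressed)]
        return times[:cut + 1]
    return times


def sample_os_cohort(n: int, rng: np.random.Generator,
                     os_model: OSModel = REFERENCE_OS_MODEL,
                     tgi: TGIPopulationModel = REFERENCE_TGI_MODEL,
                     covariate_freqs: dict | None = None,
                     two_arm: bool = False,
                     kde2_mult: float = 2.0,
                     t1_weeks: float = 12.0,
                     censoring_bounds: tuple = (50.0, 140.0)) -> pd.DataFrame:
    """Vectorized survival-only cohort: covariates, true TTG/BTS, OS records.

    A fast path for survival-side studies that do not need measured tumor
    series: individual TGI parameters are drawn lognormally, TTG/ECTS/BTS
    computed in closed form, and survival times drawn from the OS model
    with uniform study-duration censoring.  With ``two_arm`` the treatment
    arm's KDE2 is multiplied by ``kde2_mult``.
    """
    freqs = covariate_freqs or {"FEMALE": 0.35, "ECOG_GT0": 0.65,
                                "AGE_GE55": 0.72, "ASIAN": 0.13,
                                "NEVER_SMOKED": 0.20, "SQUAMOUS": 0.20}
    flags = {k: (rng.random(n) < p).astype(int) for k, p in freqs.items()}
    eta = rng.normal(0.0, tgi.omega_vector(), size=(n, 6))
    p = tgi.typical.as_array() * np.exp(eta)
    kl, kde1, l1, kde2, l2, base = p.T
    arm = np.zeros(n, int)
    if two_arm:
        arm = (rng.random(n) < 0.5).astype(int)
        kde2 = kde2 * np.where(arm == 1, kde2_mult, 1.0)
    ttg = np.log(kde2 / kl) / l2
    ects8 = np.exp(kl * 8.0 - (kde2 / l2) * (1.0 - np.exp(-l2 * 8.0)))
    bts = base * np.exp(kl * t1_weeks
                        - (kde1 / l1) * (1.0 - np.exp(-l1 * t1_weeks)))
    df = pd.DataFrame({
        "ID": [f"C{i:05d}" for i in range(n)],
        "ARM": np.where(arm == 1, "treatment", "control"),
        "TTG_WK": ttg, "BTS_CM": bts, "ECTS8": ects8,
        "AGE_GE55": flags["AGE_GE55"], "ASIAN": flags["ASIAN"],
        "ECOG_GT0": flags["ECOG_GT0"], "FEMALE": flags["FEMALE"],
        "NEVER_SMOKED": flags.get("NEVER_SMOKED", np.zeros(n, int)),
        "SQUAMOUS": flags.get("SQUAMOUS", np.zeros(n, int)),
    })
    mu = os_model.linear_predictor(df)
    t_death = np.exp(mu + os_model.scale * rng.standard_normal(n))
    duration = rng.uniform(*censoring_bounds, size=n)
    event = t_death <= duration
    df.insert(2, "TIME_WK", np.where(event, t_death, duration))
    df.insert(3, "EVENT", event.astype(int))
    return df


# ---------------------------------------------------------------------------
# Named presets

_PRESETS = {
    # covariate frequencies and median BTS from the three published studies
    "saturn_like": dict(
        n_patients=400,
        covariate_freqs={"FEMALE": 0.26, "ECOG_GT0": 0.69, "AGE_GE55": 0.70,
                         "ASIAN": 0.15, "NEVER_SMOKED": 0.18, "SQUAMOUS": 0.20},
        bts_median_cm=6.99,
        arms=(("placebo", 0.5, 1.0), ("erlotinib", 0.5, 2.0)),
    ),
    "atlas_like": dict(
        n_patients=350,
        covariate_freqs={"FEMALE": 0.48, "ECOG_GT0": 0.66, "AGE_GE55": 0.77,
                         "ASIAN": 0.13, "NEVER_SMOKED": 0.22, "SQUAMOUS": 0.15},
        bts_median_cm=6.1,
        arms=(("bev", 0.5, 1.0), ("bev+erlotinib", 0.5, 2.0)),
    ),
    "avaperl_like": dict(
        n_patients=253,
        covariate_freqs={"FEMALE": 0.43, "ECOG_GT0": 0.52, "AGE_GE55": 0.72,
                         "ASIAN": 0.12, "NEVER_SMOKED": 0.25, "SQUAMOUS": 0.05},
        bts_median_cm=5.21,
        arms=(("bev", 0.5, 1.0), ("bev+pemetrexed", 0.5, 2.0)),
    ),
}


def make_fixture(name: str, rng: np.random.Generator | None = None,
                 n_patients: int | None = None,
                 tgi: TGIPopulationModel = REFERENCE_TGI_MODEL,
                 os_model: OSModel = REFERENCE_OS_MODEL) -> SyntheticStudy:
    """Deterministic named study presets; "toy4" is a 4-patient hand-checkable
    dataset (no IIV, no noise, fully evaluable)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    if name == "toy4":
        spec = StudySpec(name="toy4", n_patients=4,
                         arms=(("control", 0.5, 1.0), ("treatment", 0.5, 2.0)),
                         evaluable_fraction=1.0)
        quiet = TGIPopulationModel(
            typical=tgi.typical,
            omega={k: 0.0 for k in tgi.omega}, sigma=0.0)
        return generate_study(spec, tgi=quiet, os_model=os_model, rng=rng)
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; options: "
                       f"{sorted(_PRESETS) + ['toy4']}")
    kwargs = dict(_PRESETS[name])
    if n_patients is not None:
        kwargs["n_patients"] = n_patients
    spec = StudySpec(name=name, **kwargs)
    return generate_study(spec, tgi=tgi, os_model=os_model, rng=rng)
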