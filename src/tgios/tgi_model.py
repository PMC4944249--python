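"""Two-phase tumor-growth-inhibition (TGI) structural model.

The model describes the sum of longest diameters (SLD, cm) of a patient's
target lesions over a first-line treatment run-in phase followed by a
maintenance phase starting at the randomization time ``t1``.  In each phase
the tumor grows exponentially at a constant rate ``KL`` while the drug kills
cells at a rate that decays exponentially from its initial value
(``KDE1``/``LAMBDA1`` during first line, ``KDE2``/``LAMBDA2`` during
maintenance).  The log-size is therefore piecewise analytic:

    0 <= t <= t1 : TS(t) = BASE * exp(KL*t - (KDE1/L1) * (1 - exp(-L1*t)))
    t  >  t1     : TS(t) = TS(t1) * exp(KL*u - (KDE2/L2) * (1 - exp(-L2*u)))

with ``u = t - t1``.  Two scalar metrics of the maintenance-phase profile
are derived per patient:

* TTG, the time to tumor regrowth: the time after randomization at which
  the profile reaches its nadir, ``ln(KDE2/KL)/LAMBDA2``.  Negative when
  ``KL > KDE2`` (the tumor regrows immediately).
* week-8 ECTS, the early change in tumor size: the model-predicted ratio
  ``TS(t1 + 8) / TS(t1)``.

All times are in weeks from the start of first-line treatment; sizes in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PARAM_NAMES = ("KL", "KDE1", "LAMBDA1", "KDE2", "LAMBDA2", "BASE")

# Parameters carrying lognormal inter-individual random effects.  LAMBDA1 is
# excluded: variability on the first-line decay rate is not identifiable from
# the sparse run-in sampling and its omega is fixed to zero.
RANDOM_EFFECT_NAMES = ("KL", "KDE1", "KDE2", "LAMBDA2", "BASE")


@dataclass(frozen=True)
class TGIIndividualParams:
    """One patient's structural parameters (all strictly positive).

    KL      growth rate (1/week), shared by both phases
    KDE1    first-line drug-effect rate (1/week)
    LAMBDA1 first-line drug-effect decay rate (1/week)
    KDE2    maintenance drug-effect rate (1/week)
    LAMBDA2 maintenance drug-effect decay rate (1/week)
    BASE    tumor size at first-line start (cm)
    """

    KL: float
    KDE1: float
    LAMBDA1: float
    KDE2: float
    LAMBDA2: float
    BASE: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "TGIIndividualParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))


@dataclass(frozen=True)
class TGIPopulationModel:
    """Population TGI model: typical values, IIV SDs and residual SD.

    ``omega`` holds the standard deviations of the lognormal inter-individual
    random effects (log scale, dimensionless); an entry of zero means the
    parameter is fixed at its typical value for every patient.  ``sigma`` is
    the SD of the additive residual error on the cm scale.
    """

    typical: TGIIndividualParams
    omega: dict = field(default_factory=dict)
    sigma: float = 0.0
    standard_errors: dict | None = None  # optional per-parameter %RSE

    def __post_init__(self) -> None:
        for name, value in self.omega.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r} in omega")
            if value < 0:
                raise ValueError(f"omega[{name!r}] must be >= 0")
        if self.omega.get("LAMBDA1", 0.0) != 0.0:
            raise ValueError("IIV on LAMBDA1 is not identifiable; omega must be 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def omega_vector(self) -> np.ndarray:
        """Omega SDs in PARAM_NAMES order (zeros where absent)."""
        return np.array([self.omega.get(n, 0.0) for n in PARAM_NAMES])

    def draw_individual(self, rng: np.random.Generator) -> TGIIndividualParams:
        """Sample one patient's parameters: typical * exp(eta), eta ~ N(0, omega^2)."""
        eta = rng.normal(0.0, self.omega_vector())
        return TGIIndividualParams.from_array(self.typical.as_array() * np.exp(eta))


# Published population estimates for the simplified TGI model fitted to the
# SATURN + ATLAS maintenance data (typical value, IIV SD, residual variance
# 0.58 cm^2).  These drive the synthetic-data generator defaults.
REFERENCE_TGI_MODEL = TGIPopulationModel(
    typical=TGIIndividualParams(
        KL=0.00464, KDE1=0.0566, LAMBDA1=0.117, KDE2=0.00412, LAMBDA2=0.0597,
        BASE=7.74,
    ),
    omega={"KL": 1.05, "KDE1": 0.699, "KDE2": 1.64, "LAMBDA2": 0.787, "BASE": 0.64},
    sigma=float(np.sqrt(0.58)),
    standard_errors={"KL": 8.59, "KDE1": 3.95, "LAMBDA1": 6.06, "KDE2": 18.2,
                     "LAMBDA2": 14.9, "BASE": 1.67},
)


@dataclass(frozen=True)
class TumorSeries:
    """One patient's longitudinal SLD measurements.

    Times are weeks from first-line start; ``t1`` is the randomization time
    (start of maintenance).  Observation times must be strictly increasing.
    """

    patient_id: str
    t1: float
    times: tuple
    sizes: tuple

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("t1 must be > 0")
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sizes, dtype=float)
        if t.shape != s.shape:
            raise ValueError("times and sizes must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("sizes must be >= 0")

    @property
    def n_obs(self) -> int:
        return len(self.times)

    def n_after_t1(self) -> int:
        return int(np.sum(np.asarray(self.times) > self.t1))

    def n_at_or_before_t1(self) -> int:
        return int(np.sum(np.asarray(self.times) <= self.t1))


@dataclass(frozen=True)
class TGIMetrics:
    """Per-patient maintenance-phase metrics: TTG (weeks from randomization,
    may be negative) and week-8 ECTS (size ratio, > 0)."""

    ttg: float
    ects8: float


def _log_size(params: TGIIndividualParams, t: np.ndarray, t1: float) -> np.ndarray:
    """log TS(t) for the two-phase profile; vectorized over t."""
    t = np.asarray(t, dtype=float)
    kl, kde1, l1, kde2, l2, base = params.as_array()
    tp1 = np.minimum(t, t1)           # time spent in phase 1
    u = np.maximum(t - t1, 0.0)       # time spent in phase 2
    log_ts = (np.log(base)
              + kl * tp1 - (kde1 / l1) * (1.0 - np.exp(-l1 * tp1))
              + kl * u - (kde2 / l2) * (1.0 - np.exp(-l2 * u)))
    return log_ts


def predict_size(params: TGIIndividualParams, t, t1: float):
    """Model-predicted tumor size (cm) at time(s) ``t`` weeks from first-line start.

    Continuous at ``t1`` by construction.  Accepts a scalar or array ``t``.
    """
    if t1 <= 0:
        raise ValueError("t1 must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(_log_size(params, t_arr, t1))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def compute_ttg(params: TGIIndividualParams) -> float:
    """Time to tumor regrowth in weeks from randomization: ln(KDE2/KL)/LAMBDA2.

    The stationary point of the maintenance-phase profile; positive iff the
    initial drug-effect rate exceeds the growth rate (KDE2 > KL), otherwise
    negative (the profile is increasing from randomization onward).
    """
    return float(np.log(params.KDE2 / params.KL) / params.LAMBDA2)


def compute_ects8(params: TGIIndividualParams, t1: float) -> float:
    """Week-8 early change in tumor size: TS(t1 + 8) / TS(t1).

    The denominator is the model-predicted size at randomization — only the
    maintenance-phase change is of interest — so the ratio depends on the
    maintenance parameters only.
    """
    if t1 <= 0:
        raise ValueError("t1 must be > 0")
    kl, l2, kde2 = params.KL, params.LAMBDA2, params.KDE2
    return float(np.exp(kl * 8.0 - (kde2 / l2) * (1.0 - np.exp(-l2 * 8.0))))


def compute_metrics(params: TGIIndividualParams, t1: float = 12.0) -> TGIMetrics:
    return TGIMetrics(ttg=compute_ttg(params), ects8=compute_ects8(params, t1))


def simulate_series(params: TGIIndividualParams, schedule: Iterable[float],
                    t1: float, sigma: float,
                    rng: np.random.Generator,
                    patient_id: str = "sim") -> TumorSeries:
    """Forward-simulate noisy SLD measurements on an assessment schedule.

    Additive Gaussian residual error with SD ``sigma`` cm, truncated at zero
    (a diameter sum cannot be negative).  Deterministic under a fixed rng
    state.
    """
    times = np.asarray(list(schedule), dtype=float)
    if times.size == 0:
        raise ValueError("schedule must contain at least one assessment time")
    if np.any(np.diff(times) <= 0):
        raise ValueError("schedule times must be strictly increasing")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    mean = predict_size(params, times, t1)
    sizes = np.maximum(mean + rng.normal(0.0, sigma, size=times.shape), 0.0)
    return TumorSeries(patient_id=patient_id, t1=float(t1),
                       times=tuple(times), sizes=tuple(sizes))


# ---------------------------------------------------------------------------
# Tumor CSV dialect: ID, TIME_WK, SIZE_CM, T1_WK (long format, one row per
# assessment).  Empty SIZE_CM fields mark missed assessments and are skipped.

TUMOR_CSV_COLUMNS = ["ID", "TIME_WK", "SIZE_CM", "T1_WK"]


def series_to_frame(series_list: Sequence[TumorSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for t, y in zip(s.times, s.sizes):
            rows.append({"ID": s.patient_id, "TIME_WK": t, "SIZE_CM": y,
                         "T1_WK": s.t1})
    return pd.DataFrame(rows, columns=TUMOR_CSV_COLUMNS)


def write_tumor_csv(series_list: Sequence[TumorSeries], path) -> None:
    series_to_frame(series_list).to_csv(path, index=False)


def read_tumor_csv(path) -> list[TumorSeries]:
    """Read the long-format tumor CSV, skipping rows with missing sizes."""
    df = pd.read_csv(path)
    missing = [c for c in TUMOR_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tumor CSV missing columns: {missing}")
    df = df.dropna(subset=["SIZE_CM"])
    out = []
    for pid, grp in df.groupby("ID", sort=False):
        grp = grp.sort_values("TIME_WK")
        t1 = float(grp["T1_WK"].iloc[0])
        out.append(TumorSeries(patient_id=str(pid), t1=t1,
                               times=tuple(grp["TIME_WK"].astype(float)),
                               sizes=tuple(grp["SIZE_CM"].astype(float))))
    return out
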