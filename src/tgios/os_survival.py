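"""Overall-survival analytics.

Covariate screening uses univariate Cox proportional-hazards regression
(Efron ties); the OS model itself is a parametric accelerated-failure-time
(AFT) regression chosen among six location-scale families — normal,
lognormal, Weibull, logistic, log-logistic and exponential — by AIC, then
reduced by backward elimination with likelihood-ratio tests at p < 0.01.

In an AFT model the covariates act additively on the (possibly
log-transformed) event time:  y = X beta + s * eps,  with y = log T for the
log families and y = T otherwise, and eps a standard error distribution
(normal, logistic, or smallest-extreme-value for Weibull/exponential).
Likelihoods are on the scale of T (the log-families include the 1/t
Jacobian) so AIC is comparable across families.  OS is modeled in weeks.

Kaplan-Meier estimation and Cox regression wrap lifelines; a vectorized
single-binary-covariate Cox-Newton solver is provided for the trial
simulator, where hundreds of thousands of two-arm fits are needed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import optimize, stats

WEEKS_PER_MONTH = 30.4375 / 7.0

AFT_FAMILIES = ("normal", "lognormal", "weibull", "logistic", "log-logistic",
                "exponential")

#: Hazard-ratio reporting units for screening: value to multiply the raw
#: coefficient by before exponentiating (e.g. HR per 8 weeks of TTG).
SCREENING_UNITS = {
    "TTG_WK": 8.0,       # per 8 weeks of TTG
    "BTS_CM": 2.0,       # per 2 cm of tumor size at randomization
    "ECTS8": 0.1,        # per 10 % of size relative to randomization
    "AGE_YR": 10.0,      # per 10 years of age
}

FINAL_MODEL_COVARIATES = ("TTG_WK", "BTS_CM", "AGE_GE55", "ASIAN", "ECOG_GT0",
                          "FEMALE")

SURVIVAL_CSV_COLUMNS = ["ID", "TIME_WK", "EVENT", "TTG_WK", "BTS_CM",
                        "AGE_GE55", "ASIAN", "ECOG_GT0", "FEMALE"]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's right-censored survival datum with covariates."""

    patient_id: str
    time: float           # weeks, > 0
    event: bool           # True = death observed
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError("time must be finite and > 0")


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"ID": r.patient_id, "TIME_WK": r.time, "EVENT": int(r.event)}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list:
    cov_cols = [c for c in df.columns if c not in ("ID", "TIME_WK", "EVENT")]
    return [
        SurvivalRecord(patient_id=str(row["ID"]), time=float(row["TIME_WK"]),
                       event=bool(row["EVENT"]),
                       covariates={c: row[c] for c in cov_cols})
        for _, row in df.iterrows()
    ]


def write_survival_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_survival_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("ID", "TIME_WK", "EVENT") if c not in df.columns]
    if missing:
        raise ValueError(f"survival CSV missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMEstimate:
    times: np.ndarray        # distinct event times (drops)
    survival: np.ndarray     # S(t) just after each drop
    median: float            # weeks; nan if S never reaches 0.5
    n: int
    n_events: int

    def evaluate(self, grid) -> np.ndarray:
        """Step-function survival probability at arbitrary times."""
        idx = np.searchsorted(self.times, np.asarray(grid, float), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def km_estimate(times, events) -> KMEstimate:
    """Product-limit estimator; median = earliest t with S(t) <= 0.5."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.size == 0:
        raise ValueError("need at least one record")
    if not events.any():
        warnings.warn("all records censored: survival curve has no drops",
                      stacklevel=2)
        return KMEstimate(times=np.array([]), survival=np.array([]),
                          median=float("nan"), n=times.size, n_events=0)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_.iloc[:, 0]
    drops = sf[sf.diff().fillna(0) < 0]
    med = kmf.median_survival_time_
    return KMEstimate(times=drops.index.to_numpy(float),
                      survival=drops.to_numpy(float),
                      median=float(med) if np.isfinite(med) else float("nan"),
                      n=times.size, n_events=int(events.sum()))


def km_curve_fast(times, events):
    """Vectorized product-limit curve: (event_times, survival_after_drop).

    Numpy-only path for the replicate engine; agrees with ``km_estimate``.
    """
    order = np.argsort(times, kind="stable")
    t = np.asarray(times, float)[order]
    e = np.asarray(events, bool)[order]
    ut, first = np.unique(t, return_index=True)
    n = t.size
    at_risk = n - first
    d = np.add.reduceat(e.astype(float), first)
    mask = d > 0
    surv = np.cumprod(1.0 - d[mask] / at_risk[mask])
    return ut[mask], surv


def km_median_fast(times, events) -> float:
    et, s = km_curve_fast(times, events)
    below = s <= 0.5
    return float(et[np.argmax(below)]) if below.any() else float("nan")


# ---------------------------------------------------------------------------
# Cox regression


@dataclass
class CoxResult:
    covariate: str
    hr: float                 # per reporting unit
    ci95: tuple
    score: float              # likelihood-ratio chi-square statistic
    p: float
    sign: str                 # "+" increased risk, "-" decreased risk
    coef: float               # raw per-unit log-hazard coefficient
    unit: float = 1.0
    flagged: str | None = None


def cox_fit(df: pd.DataFrame, covariate: str, unit: float | None = None,
            time_col: str = "TIME_WK", event_col: str = "EVENT") -> CoxResult:
    """Univariate Cox PH fit (Efron ties) with unit-scaled HR reporting.

    ``unit`` rescales the reported HR and CI to "per unit increase" (e.g.
    per 8 weeks of TTG); the score statistic and p-value are scale-free.
    """
    if unit is None:
        unit = SCREENING_UNITS.get(covariate, 1.0)
    data = df[[time_col, event_col, covariate]].dropna()
    if not data[event_col].astype(bool).any():
        raise ValueError("no events observed")
    cph = CoxPHFitter()
    flagged = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(data, duration_col=time_col, event_col=event_col)
        except Exception as exc:  # monotone likelihood / separation
            return CoxResult(covariate=covariate, hr=float("nan"),
                             ci95=(float("nan"), float("nan")),
                             score=float("nan"), p=float("nan"), sign="?",
                             coef=float("nan"), unit=unit,
                             flagged=f"fit failed: {exc}")
    beta = float(cph.params_[covariate])
    se = float(cph.standard_errors_[covariate])
    lr = cph.log_likelihood_ratio_test()
    hr = float(np.exp(beta * unit))
    lo, hi = np.exp((beta - 1.96 * se) * unit), np.exp((beta + 1.96 * se) * unit)
    return CoxResult(covariate=covariate, hr=hr,
                     ci95=(float(min(lo, hi)), float(max(lo, hi))),
                     score=float(lr.test_statistic), p=float(lr.p_value),
                     sign="+" if beta > 0 else "-", coef=beta, unit=unit,
                     flagged=flagged)


def screen_covariates(df: pd.DataFrame, candidates, alpha: float = 0.05,
                      time_col: str = "TIME_WK",
                      event_col: str = "EVENT") -> list:
    """One univariate Cox fit per candidate, ranked by descending score.

    A candidate is "significant" when its likelihood-ratio p-value is below
    ``alpha`` (default 0.05, the full-model inclusion threshold).
    """
    results = [cox_fit(df, c, time_col=time_col, event_col=event_col)
               for c in candidates]
    results.sort(key=lambda r: (-r.score if np.isfinite(r.score) else np.inf))
    return results


def significant_covariates(results, alpha: float = 0.05) -> list:
    return [r.covariate for r in results
            if np.isfinite(r.p) and r.p < alpha]


def cox_hr_binary(times, events, group):
    """Fast Efron-ties Cox fit for one binary covariate (treatment arm).

    Newton iteration on the 1-parameter partial likelihood, fully
    vectorized; returns (hr, lr_statistic, p_value).  Used by the trial
    simulator where lifelines per-replicate overhead would dominate.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    g = np.asarray(group, int)
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    ut, first = np.unique(t, return_index=True)
    n = t.size
    # at-risk counts by group at each distinct time
    cum1 = np.concatenate([[0], np.cumsum(g)])
    cum1_at = cum1[first]
    n_at = n - first
    n1_at = cum1[-1] - cum1_at
    n0_at = n_at - n1_at
    d1 = np.add.reduceat((e & (g == 1)).astype(float), first)
    d0 = np.add.reduceat((e & (g == 0)).astype(float), first)
    d = d0 + d1
    mask = d > 0
    n0r, n1r, d0r, d1r, dr = (a[mask] for a in (n0_at, n1_at, d0, d1, d))
    # Efron: one log term per (event time j, l = 0..d_j-1)
    reps = dr.astype(int)
    j_idx = np.repeat(np.arange(dr.size), reps)
    l = np.concatenate([np.arange(k) for k in reps]) if reps.size else np.array([])
    frac = l / dr[j_idx]
    A = n0r[j_idx] - frac * d0r[j_idx]
    B = n1r[j_idx] - frac * d1r[j_idx]
    s1 = float(d1r.sum())

    def loglik(beta):
        eb = np.exp(beta)
        return s1 * beta - np.sum(np.log(A + B * eb))

    beta = 0.0
    for _ in range(30):
        eb = np.exp(beta)
        denom = A + B * eb
        w = B * eb / denom
        grad = s1 - w.sum()
        hess = -np.sum(w * (1.0 - w))
        if hess >= -1e-12:
            break
        step = np.clip(-grad / hess, -2.0, 2.0)
        beta += step
        if abs(step) < 1e-10:
            break
    beta = float(np.clip(beta, -30.0, 30.0))
    lr = 2.0 * (loglik(beta) - loglik(0.0))
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return float(np.exp(beta)), float(lr), p


# ---------------------------------------------------------------------------
# Parametric AFT (location-scale) survival regression


# family -> (log time?, logpdf(z), logsf(z), median z of the error dist)
_LN2 = float(np.log(np.log(2.0)))


def _gumbel_min_logpdf(z):
    # smallest-extreme-value errors (Weibull/exponential AFT); clamp the
    # exponent so line searches far from the optimum stay finite
    return z - np.exp(np.minimum(z, 600.0))


def _gumbel_min_logsf(z):
    return -np.exp(np.minimum(z, 600.0))


_FAMILY = {
    "normal":       (False, stats.norm.logpdf, stats.norm.logsf, 0.0),
    "lognormal":    (True, stats.norm.logpdf, stats.norm.logsf, 0.0),
    "weibull":      (True, _gumbel_min_logpdf, _gumbel_min_logsf, _LN2),
    "logistic":     (False, stats.logistic.logpdf, stats.logistic.logsf, 0.0),
    "log-logistic": (True, stats.logistic.logpdf, stats.logistic.logsf, 0.0),
    "exponential":  (True, _gumbel_min_logpdf, _gumbel_min_logsf, _LN2),
}


@dataclass
class OSModel:
    """Fitted parametric OS regression.

    ``coefficients`` maps covariate -> estimate on the model's (log-)time
    scale, including "Intercept"; ``log_scale`` is log of the scale s;
    ``covariance`` is over (coefficients..., log_scale) in ``param_names``
    order (the exponential family has no free scale).
    """

    family: str
    coefficients: dict
    log_scale: float
    covariance: np.ndarray | None
    aic: float
    log_likelihood: float = float("nan")
    n: int = 0
    n_events: int = 0
    standard_errors: dict | None = None
    p_values: dict | None = None
    flagged: str | None = None

    @property
    def param_names(self) -> list:
        names = list(self.coefficients)
        if self.family != "exponential":
            names.append("Log(scale)")
        return names

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    @property
    def covariate_names(self) -> list:
        return [c for c in self.coefficients if c != "Intercept"]

    def linear_predictor(self, covariates) -> np.ndarray:
        """X beta (location mu) for a covariate mapping or DataFrame."""
        if isinstance(covariates, dict):
            covariates = pd.DataFrame([covariates])
        lp = np.full(len(covariates), self.coefficients["Intercept"])
        for name in self.covariate_names:
            if name not in covariates:
                raise KeyError(f"covariate {name!r} missing")
            lp = lp + self.coefficients[name] * covariates[name].to_numpy(float)
        return lp

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "log_scale": float(self.log_scale),
            "covariance": None if self.covariance is None
            else np.asarray(self.covariance).tolist(),
            "aic": float(self.aic),
            "log_likelihood": float(self.log_likelihood),
            "n": self.n, "n_events": self.n_events,
            "standard_errors": self.standard_errors,
            "p_values": self.p_values,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "OSModel":
        cov = d.get("covariance")
        return cls(family=d["family"], coefficients=dict(d["coefficients"]),
                   log_scale=float(d["log_scale"]),
                   covariance=None if cov is None else np.asarray(cov, float),
                   aic=float(d.get("aic", float("nan"))),
                   log_likelihood=float(d.get("log_likelihood", float("nan"))),
                   n=int(d.get("n", 0)), n_events=int(d.get("n_events", 0)),
                   standard_errors=d.get("standard_errors"),
                   p_values=d.get("p_values"))

    @classmethod
    def load(cls, path) -> "OSModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# Published final OS model (lognormal AFT, weeks): intercept, TTG (weeks),
# baseline tumor size at randomization (cm), age >= 55, Asian ethnicity,
# ECOG > 0, female, and log-scale.  The parameter covariance is taken as
# diagonal in the published standard errors (correlations unavailable).
_REF_OS_COEF = {
    "Intercept": 4.3776, "TTG_WK": 0.0139, "BTS_CM": -0.0437,
    "AGE_GE55": -0.2519, "ASIAN": 0.2324, "ECOG_GT0": -0.157,
    "FEMALE": 0.1437,
}
_REF_OS_SE = {
    "Intercept": 0.065883, "TTG_WK": 0.000889, "BTS_CM": 0.005014,
    "AGE_GE55": 0.049494, "ASIAN": 0.066116, "ECOG_GT0": 0.045344,
    "FEMALE": 0.045306, "Log(scale)": 0.024079,
}
REFERENCE_OS_MODEL = OSModel(
    family="lognormal",
    coefficients=dict(_REF_OS_COEF),
    log_scale=-0.3017,
    covariance=np.diag([_REF_OS_SE[k] ** 2
                        for k in list(_REF_OS_COEF) + ["Log(scale)"]]),
    aic=float("nan"),
    standard_errors=dict(_REF_OS_SE),
)


def _aft_negloglik(params, X, y, event, family, log_time):
    _, logpdf, logsf, _ = _FAMILY[family]
    if family == "exponential":
        beta, log_s = params, 0.0
    else:
        beta, log_s = params[:-1], params[-1]
    s = np.exp(log_s)
    z = (y - X @ beta) / s
    ll = np.sum(logpdf(z[event]) - log_s)
    ll += np.sum(logsf(z[~event]))
    if log_time:
        ll -= np.sum(y[event])  # Jacobian: density on the scale of T
    return -ll


def _fd_hessian(fun, x, h=1e-4):
    n = x.size
    H = np.zeros((n, n))
    f0 = fun(x)
    fp = np.array([fun(x + h * np.eye(n)[i]) for i in range(n)])
    fm = np.array([fun(x - h * np.eye(n)[i]) for i in range(n)])
    for i in range(n):
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
        for j in range(i + 1, n):
            e = h * (np.eye(n)[i] + np.eye(n)[j])
            H[i, j] = H[j, i] = (fun(x + e) + fun(x - e) + 2 * f0
                                 - fp[i] - fm[i] - fp[j] - fm[j]) / (2 * h * h)
    return H


def fit_aft(df: pd.DataFrame, covariates, family: str = "lognormal",
            time_col: str = "TIME_WK", event_col: str = "EVENT",
            compute_covariance: bool = True) -> OSModel:
    """Right-censored MLE of the location-scale AFT regression.

    Raises on an empty event set or a rank-deficient design matrix (the
    offending columns are named).  AIC = -2 loglik + 2 k with k counting the
    regression coefficients plus the scale (absent for exponential).
    """
    if family not in _FAMILY:
        raise ValueError(f"unknown family {family!r}; choose from {AFT_FAMILIES}")
    covariates = list(covariates)
    data = df[[time_col, event_col] + covariates].dropna()
    event = data[event_col].to_numpy(bool)
    if not event.any():
        raise ValueError("no events observed")
    t = data[time_col].to_numpy(float)
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    log_time = _FAMILY[family][0]
    y = np.log(t) if log_time else t
    X = np.column_stack([np.ones(len(data))]
                        + [data[c].to_numpy(float) for c in covariates])
    names = ["Intercept"] + covariates
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear columns via QR pivoting on the Gram matrix
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"design matrix is rank deficient; check {bad or names}")

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    s0 = max(float(np.std(resid[event])) if event.sum() > 1 else 1.0, 1e-2)
    if family == "exponential":
        x0 = beta0
    else:
        x0 = np.concatenate([beta0, [np.log(s0)]])

    res = optimize.minimize(_aft_negloglik, x0,
                            args=(X, y, event, family, log_time),
                            method="BFGS",
                            options={"gtol": 1e-7, "maxiter": 500})
    x_hat = res.x
    ll = -float(res.fun)
    k = x_hat.size
    flagged = None if res.success else f"optimizer: {res.message}"

    cov = None
    ses = None
    pvals = None
    if compute_covariance:
        H = _fd_hessian(lambda p: _aft_negloglik(p, X, y, event, family,
                                                 log_time), x_hat)
        try:
            cov = np.linalg.inv(0.5 * (H + H.T))
            diag = np.diag(cov)
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError("non-PD information")
            se = np.sqrt(diag)
            pnames = names + ([] if family == "exponential" else ["Log(scale)"])
            ses = dict(zip(pnames, map(float, se)))
            pvals = {nm: float(2 * stats.norm.sf(abs(x_hat[i] / se[i])))
                     for i, nm in enumerate(pnames)}
        except np.linalg.LinAlgError:
            cov = None
            flagged = (flagged or "") + " degenerate information matrix"

    n_coef = len(names)
    return OSModel(
        family=family,
        coefficients=dict(zip(names, map(float, x_hat[:n_coef]))),
        log_scale=0.0 if family == "exponential" else float(x_hat[-1]),
        covariance=cov, aic=-2.0 * ll + 2.0 * k, log_likelihood=ll,
        n=len(data), n_events=int(event.sum()),
        standard_errors=ses, p_values=pvals, flagged=flagged,
    )


def select_family(df: pd.DataFrame, covariates, families=AFT_FAMILIES,
                  time_col: str = "TIME_WK",
                  event_col: str = "EVENT") -> list:
    """Fit every candidate family; return OSModels ranked by ascending AIC."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_aft(df, covariates, family=fam, time_col=time_col,
                                event_col=event_col,
                                compute_covariance=False))
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"{fam} fit failed: {exc}", stacklevel=2)
    fits.sort(key=lambda m: m.aic)
    return fits


def backward_eliminate(df: pd.DataFrame, covariates, family: str = "lognormal",
                       alpha: float = 0.01, time_col: str = "TIME_WK",
                       event_col: str = "EVENT"):
    """Backward stepwise elimination by likelihood-ratio test.

    At each step the covariate whose removal degrades the fit least is
    dropped if the 1-df LR test of its removal is not significant at
    ``alpha``; stops when removing any remaining covariate would be
    significantly worse.  The intercept is always retained.  Returns
    (final OSModel, elimination trace).
    """
    remaining = list(covariates)
    trace = []
    current = fit_aft(df, remaining, family=family, time_col=time_col,
                      event_col=event_col, compute_covariance=False)
    while remaining:
        pvals = {}
        for c in remaining:
            reduced = fit_aft(df, [x for x in remaining if x != c],
                              family=family, time_col=time_col,
                              event_col=event_col, compute_covariance=False)
            lr = 2.0 * (current.log_likelihood - reduced.log_likelihood)
            pvals[c] = float(stats.chi2.sf(max(lr, 0.0), df=1))
        worst = max(remaining, key=lambda c: pvals[c])
        if pvals[worst] < alpha:
            break
        remaining.remove(worst)
        trace.append({"removed": worst, "p": pvals[worst],
                      "kept": list(remaining)})
        current = fit_aft(df, remaining, family=family, time_col=time_col,
                          event_col=event_col, compute_covariance=False)
    final = fit_aft(df, remaining, family=family, time_col=time_col,
                    event_col=event_col, compute_covariance=True)
    return final, trace


def predict_median(model: OSModel, covariates) -> np.ndarray | float:
    """Closed-form median survival time at a covariate vector.

    For the lognormal family the median is exp(X beta); in general it is the
    location plus scale times the error-distribution median, back-transformed
    for log-time families.
    """
    lp = model.linear_predictor(covariates)
    z_med = _FAMILY[model.family][3]
    log_time = _FAMILY[model.family][0]
    med = lp + model.scale * z_med
    out = np.exp(med) if log_time else med
    return float(out[0]) if out.size == 1 else out


def weeks_to_months(weeks):
    return np.asarray(weeks, float) * 7.0 / 30.4375
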