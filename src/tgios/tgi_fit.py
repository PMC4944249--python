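"""Population (nonlinear mixed-effects) estimation of the TGI model.

The marginal likelihood integrates lognormal random effects on KL, KDE1,
KDE2, LAMBDA2 and BASE (none on LAMBDA1) out of the per-patient data
likelihood under additive Gaussian residual error.  The integral is
approximated by Laplace's method: for each patient the joint negative log
density is minimized over the random-effect vector eta (a penalized
least-squares problem in log-parameter space, solved by damped Gauss-Newton,
vectorized across patients), and the curvature at the mode supplies the
Gaussian correction.  The outer optimization over population parameters
(log typical values, log omega SDs, log sigma) uses L-BFGS-B.

Empirical-Bayes ("posthoc") individual estimates are the inner modes;
eta-shrinkage is reported as 100*(1 - SD(eta)/omega) and residual shrinkage
as 100*(1 - SD(IWRES)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .tgi_model import (
    PARAM_NAMES,
    RANDOM_EFFECT_NAMES,
    TGIIndividualParams,
    TGIPopulationModel,
    TumorSeries,
)

_RE_IDX = np.array([PARAM_NAMES.index(n) for n in RANDOM_EFFECT_NAMES])
_N_RE = len(RANDOM_EFFECT_NAMES)
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class TGIDataset:
    """A collection of tumor series with per-patient evaluability flags."""

    series: list
    evaluable: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.evaluable:
            self.evaluable = {s.patient_id: _is_evaluable(s) for s in self.series}

    @property
    def n_patients(self) -> int:
        return len(self.series)

    def evaluable_series(self) -> list:
        return [s for s in self.series if self.evaluable.get(s.patient_id)]


def _is_evaluable(s: TumorSeries) -> bool:
    # At least one measurement after randomization (to see the maintenance
    # phase) and one at/before it (to anchor BASE and the first-line decline).
    return s.n_after_t1() >= 1 and s.n_at_or_before_t1() >= 1


def filter_evaluable(dataset: TGIDataset) -> TGIDataset:
    """Retain patients with >= 1 post-randomization and >= 1 earlier measurement.

    Returns a new dataset; emits a warning (not an error) if nothing remains.
    """
    kept = [s for s in dataset.series if _is_evaluable(s)]
    if not kept:
        warnings.warn("no evaluable patients after filtering", stacklevel=2)
    return TGIDataset(series=kept, evaluable={s.patient_id: True for s in kept})


def evaluable_fraction(dataset: TGIDataset) -> float:
    if not dataset.series:
        return float("nan")
    return sum(map(_is_evaluable, dataset.series)) / len(dataset.series)


@dataclass
class EstimationSettings:
    maxiter: int = 400
    xtol: float = 1e-4          # relative parameter-change tolerance
    gtol: float = 1e-5
    compute_se: bool = True
    inner_maxiter: int = 60
    inner_gtol: float = 1e-9
    min_log_omega: float = np.log(1e-3)


@dataclass
class TGIFitResult:
    population: TGIPopulationModel
    individual: dict                     # patient_id -> TGIIndividualParams
    log_likelihood: float
    standard_errors: dict | None         # %RSE per parameter (incl. "sigma")
    shrinkage: dict                      # % per random-effect param + "residual"
    convergence: dict
    etas: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Flattened data layout shared by all inner computations


class _Stacked:
    def __init__(self, series_list):
        self.n_pat = len(series_list)
        self.t = np.concatenate([np.asarray(s.times, float) for s in series_list])
        self.y = np.concatenate([np.asarray(s.sizes, float) for s in series_list])
        self.pidx = np.concatenate(
            [np.full(s.n_obs, i) for i, s in enumerate(series_list)]
        ).astype(np.intp)
        self.t1 = np.array([s.t1 for s in series_list])[self.pidx]
        self.n_obs = np.array([s.n_obs for s in series_list], dtype=float)
        self.ids = [s.patient_id for s in series_list]


def _model_and_jac(log_typ: np.ndarray, eta: np.ndarray, st: _Stacked):
    """Batched model prediction f and Jacobian df/deta at each observation.

    eta has shape (n_pat, n_re); returns (f, J) with J of shape (n_obs, n_re).
    """
    log_p = np.tile(log_typ, (st.n_pat, 1))
    log_p[:, _RE_IDX] += eta
    # keep parameters in a physically meaningful range; avoids overflow and
    # degenerate rates during line searches far from the optimum
    np.clip(log_p, -25.0, 25.0, out=log_p)
    p = np.exp(log_p)[st.pidx]              # (n_obs, 6)
    kl, kde1, l1, kde2, l2, base = p.T
    tp1 = np.minimum(st.t, st.t1)
    u = np.maximum(st.t - st.t1, 0.0)
    e1 = np.exp(-l1 * tp1)
    e2 = np.exp(-l2 * u)
    log_ts = (np.log(base) + kl * tp1 - (kde1 / l1) * (1.0 - e1)
              + kl * u - (kde2 / l2) * (1.0 - e2))
    f = np.exp(np.clip(log_ts, -30.0, 30.0))
    # d log f / d p for each structural parameter
    d = np.empty((st.t.size, 6))
    d[:, 0] = tp1 + u                                            # KL
    d[:, 1] = -(1.0 - e1) / l1                                   # KDE1
    d[:, 2] = (kde1 / l1) * ((1.0 - e1) / l1 - tp1 * e1)         # LAMBDA1
    d[:, 3] = -(1.0 - e2) / l2                                   # KDE2
    d[:, 4] = (kde2 / l2) * ((1.0 - e2) / l2 - u * e2)           # LAMBDA2
    d[:, 5] = 1.0 / base                                         # BASE
    # chain rule to eta (log scale): df/deta_k = f * dlogf/dp_k * p_k
    J = f[:, None] * d[:, _RE_IDX] * p[:, _RE_IDX]
    return f, J


def _segment_sum(values: np.ndarray, pidx: np.ndarray, n_pat: int) -> np.ndarray:
    out = np.zeros((n_pat,) + values.shape[1:])
    np.add.at(out, pidx, values)
    return out


def _inner_objective(log_typ, eta, sigma2, inv_om2, st: _Stacked):
    """Per-patient joint negative log density g_i(eta) (up to full constants)."""
    f, _ = _model_and_jac(log_typ, eta, st)
    r = st.y - f
    sse = _segment_sum(r * r, st.pidx, st.n_pat)
    pen = 0.5 * np.sum(eta * eta * inv_om2, axis=1)
    return 0.5 * sse / sigma2 + pen


def _solve_inner(log_typ, eta0, sigma2, inv_om2, st: _Stacked,
                 settings: EstimationSettings):
    """Damped Gauss-Newton over eta, vectorized across patients."""
    eta = eta0.copy()
    lam = np.full(st.n_pat, 1e-3)
    g = _inner_objective(log_typ, eta, sigma2, inv_om2, st)
    eye = np.eye(_N_RE)
    for _ in range(settings.inner_maxiter):
        f, J = _model_and_jac(log_typ, eta, st)
        r = st.y - f
        grad = -_segment_sum(J * r[:, None], st.pidx, st.n_pat) / sigma2 \
            + eta * inv_om2
        if np.max(np.abs(grad)) < settings.inner_gtol:
            break
        JtJ = _segment_sum(J[:, :, None] * J[:, None, :], st.pidx, st.n_pat)
        H = JtJ / sigma2
        H[:, np.arange(_N_RE), np.arange(_N_RE)] += inv_om2
        step = -np.linalg.solve(
            H + lam[:, None, None] * eye, grad[:, :, None]
        )[:, :, 0]
        g_new = _inner_objective(log_typ, eta + step, sigma2, inv_om2, st)
        improved = g_new < g
        eta[improved] += step[improved]
        g = np.where(improved, g_new, g)
        lam = np.where(improved, np.maximum(lam * 0.3, 1e-8), lam * 5.0)
        if not improved.any() and np.min(lam) > 1e8:
            break
    return eta, g


def _laplace_hessians(log_typ, eta, sigma2, inv_om2, st: _Stacked):
    """Exact Hessian of g_i at the mode via finite differences of df/deta."""
    f, J = _model_and_jac(log_typ, eta, st)
    r = st.y - f
    JtJ = _segment_sum(J[:, :, None] * J[:, None, :], st.pidx, st.n_pat)
    second = np.zeros_like(JtJ)
    h = 1e-4
    for k in range(_N_RE):
        dp = eta.copy()
        dm = eta.copy()
        dp[:, k] += h
        dm[:, k] -= h
        _, Jp = _model_and_jac(log_typ, dp, st)
        _, Jm = _model_and_jac(log_typ, dm, st)
        d2f = (Jp - Jm) / (2.0 * h)            # (n_obs, n_re) = T[:, :, k]
        second[:, :, k] = _segment_sum(d2f * r[:, None], st.pidx, st.n_pat)
    second = 0.5 * (second + second.transpose(0, 2, 1))
    H = (JtJ - second) / sigma2
    H[:, np.arange(_N_RE), np.arange(_N_RE)] += inv_om2
    return H


def _neg_marginal_loglik(x, st: _Stacked, eta_cache, settings):
    """Sum over patients of the Laplace-approximated -log L_i."""
    log_typ = x[:6]
    log_om = x[6:6 + _N_RE]
    sigma2 = np.exp(2.0 * x[-1])
    inv_om2 = np.exp(-2.0 * log_om)
    eta, g = _solve_inner(log_typ, eta_cache["eta"], sigma2, inv_om2, st,
                          settings)
    eta_cache["eta"] = eta
    H = _laplace_hessians(log_typ, eta, sigma2, inv_om2, st)
    sign, logdet = np.linalg.slogdet(H)
    if np.any(sign <= 0):
        # Saddle/indefinite curvature away from the optimum: fall back to the
        # PSD Gauss-Newton curvature for those patients.
        _, J = _model_and_jac(log_typ, eta, st)
        JtJ = _segment_sum(J[:, :, None] * J[:, None, :], st.pidx, st.n_pat)
        Hgn = JtJ / sigma2
        Hgn[:, np.arange(_N_RE), np.arange(_N_RE)] += inv_om2
        bad = sign <= 0
        H[bad] = Hgn[bad]
        sign, logdet = np.linalg.slogdet(H)
    const = (0.5 * st.n_obs * (_LOG2PI + 2.0 * x[-1])
             + np.sum(log_om) + 0.5 * _N_RE * _LOG2PI)
    neg_ll = g + const + 0.5 * logdet - 0.5 * _N_RE * _LOG2PI
    return float(np.sum(neg_ll))


def marginal_loglik(population: TGIPopulationModel, series_list,
                    settings: EstimationSettings | None = None) -> float:
    """Laplace marginal log-likelihood of a dataset at given population values.

    Exposed so the approximation can be compared against direct numerical
    integration of the random effects on small problems.
    """
    settings = settings or EstimationSettings()
    st = _Stacked(series_list)
    x = _pack(population)
    cache = {"eta": np.zeros((st.n_pat, _N_RE))}
    return -_neg_marginal_loglik(x, st, cache, settings)


def _pack(population: TGIPopulationModel) -> np.ndarray:
    log_typ = np.log(population.typical.as_array())
    om = np.array([population.omega.get(n, 0.5) for n in RANDOM_EFFECT_NAMES])
    return np.concatenate([log_typ, np.log(np.maximum(om, 1e-3)),
                           [np.log(max(population.sigma, 1e-3))]])


def _unpack(x: np.ndarray) -> TGIPopulationModel:
    typ = TGIIndividualParams.from_array(np.exp(x[:6]))
    omega = dict(zip(RANDOM_EFFECT_NAMES, np.exp(x[6:6 + _N_RE])))
    omega["LAMBDA1"] = 0.0
    return TGIPopulationModel(typical=typ, omega=omega, sigma=float(np.exp(x[-1])))


def fit_population(dataset: TGIDataset, init: TGIPopulationModel,
                   settings: EstimationSettings | None = None) -> TGIFitResult:
    """Maximize the Laplace marginal likelihood over population parameters.

    Non-convergence never raises: the best-found estimates are returned with
    ``convergence["converged"] = False``.
    """
    settings = settings or EstimationSettings()
    series_list = dataset.evaluable_series()
    if len(series_list) < 2:
        raise ValueError("need at least two evaluable patients")
    st = _Stacked(series_list)
    x0 = _pack(init)
    cache = {"eta": np.zeros((st.n_pat, _N_RE))}

    lb = np.full(x0.size, -np.inf)
    ub = np.full(x0.size, np.inf)
    lb[6:6 + _N_RE] = settings.min_log_omega
    ub[6:6 + _N_RE] = np.log(5.0)
    lb[-1] = np.log(1e-3)

    res = optimize.minimize(
        _neg_marginal_loglik, x0, args=(st, cache, settings),
        method="L-BFGS-B", bounds=list(zip(lb, ub)),
        options={"maxiter": settings.maxiter, "ftol": 1e-9,
                 "gtol": settings.gtol, "eps": 1e-5},
    )
    x_hat = res.x
    population = _unpack(x_hat)

    # final posthoc pass at the optimum
    log_typ = x_hat[:6]
    sigma2 = np.exp(2.0 * x_hat[-1])
    inv_om2 = np.exp(-2.0 * x_hat[6:6 + _N_RE])
    eta, _ = _solve_inner(log_typ, cache["eta"], sigma2, inv_om2, st, settings)

    individual = {}
    for i, pid in enumerate(st.ids):
        log_p = log_typ.copy()
        log_p[_RE_IDX] += eta[i]
        individual[pid] = TGIIndividualParams.from_array(np.exp(log_p))

    shrink = _shrinkage_from_etas(eta, population, log_typ, st)
    se = None
    if settings.compute_se:
        se = _outer_standard_errors(x_hat, st, cache, settings, lb, ub)

    return TGIFitResult(
        population=TGIPopulationModel(
            typical=population.typical, omega=population.omega,
            sigma=population.sigma,
            standard_errors=None if se is None else
            {k: v for k, v in se.items() if k in PARAM_NAMES},
        ),
        individual=individual,
        log_likelihood=-res.fun,
        standard_errors=se,
        shrinkage=shrink,
        convergence={"converged": bool(res.success), "message": str(res.message),
                     "n_iter": int(res.nit), "n_patients": st.n_pat},
        etas={pid: eta[i].copy() for i, pid in enumerate(st.ids)},
    )


def _shrinkage_from_etas(eta, population, log_typ, st: _Stacked) -> dict:
    out = {}
    for k, name in enumerate(RANDOM_EFFECT_NAMES):
        om = population.omega.get(name, 0.0)
        if om > 0:
            out[name] = 100.0 * (1.0 - eta[:, k].std(ddof=1) / om)
    f, _ = _model_and_jac(log_typ, eta, st)
    iwres = (st.y - f) / population.sigma
    out["residual"] = 100.0 * (1.0 - iwres.std(ddof=1))
    return out


def _outer_standard_errors(x_hat, st, cache, settings, lb, ub) -> dict | None:
    """%RSE from the observed information of the outer objective.

    Central-difference Hessian over the log-scale parameters; for a
    log-parameterized quantity the SE of the log is the relative SE on the
    natural scale.
    """
    n = x_hat.size
    h = 1e-3
    def fval(x):
        return _neg_marginal_loglik(x, st, {"eta": cache["eta"].copy()},
                                    settings)
    H = np.zeros((n, n))
    f0 = fval(x_hat)
    f_plus = np.empty(n)
    f_minus = np.empty(n)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h
        f_plus[i] = fval(x_hat + ei)
        f_minus[i] = fval(x_hat - ei)
        H[i, i] = (f_plus[i] - 2 * f0 + f_minus[i]) / h**2
    for i in range(n):
        ei = np.zeros(n); ei[i] = h
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h
            fpp = fval(x_hat + ei + ej)
            fmm = fval(x_hat - ei - ej)
            H[i, j] = H[j, i] = (fpp + fmm + 2 * f0
                                 - f_plus[i] - f_minus[i]
                                 - f_plus[j] - f_minus[j]) / (2 * h * h)
    try:
        cov = np.linalg.inv(0.5 * (H + H.T))
    except np.linalg.LinAlgError:
        return None
    se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    names = list(PARAM_NAMES) + [f"omega_{n}" for n in RANDOM_EFFECT_NAMES] \
        + ["sigma"]
    return {name: 100.0 * s for name, s in zip(names, se_log)}


def posthoc(population: TGIPopulationModel, series: TumorSeries,
            settings: EstimationSettings | None = None) -> TGIIndividualParams:
    """Empirical-Bayes (conditional-mode) parameter estimates for one patient.

    Parameters with omega = 0 stay at their typical values.  Raises if the
    inner optimization fails to reduce the objective to a finite value.
    """
    settings = settings or EstimationSettings()
    st = _Stacked([series])
    log_typ = np.log(population.typical.as_array())
    om = np.array([population.omega.get(n, 0.0) for n in RANDOM_EFFECT_NAMES])
    inv_om2 = np.where(om > 0, 1.0 / np.maximum(om, 1e-12) ** 2, 1e12)
    sigma2 = max(population.sigma, 1e-6) ** 2
    eta0 = np.zeros((1, _N_RE))
    eta, g = _solve_inner(log_typ, eta0, sigma2, inv_om2, st, settings)
    if not np.all(np.isfinite(g)):
        raise RuntimeError(f"posthoc optimization failed for {series.patient_id}")
    eta = np.where(om > 0, eta[0], 0.0)
    values = population.typical.as_array()   # omega = 0 -> typical, exactly
    values[_RE_IDX] = np.where(om > 0, values[_RE_IDX] * np.exp(eta),
                               values[_RE_IDX])
    return TGIIndividualParams.from_array(values)


def compute_shrinkage(result: TGIFitResult) -> dict:
    """Eta-shrinkage (%) per random-effect parameter plus residual shrinkage."""
    return dict(result.shrinkage)
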