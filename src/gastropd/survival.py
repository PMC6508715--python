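"""Parametric time-to-event models for metastasis appearance and overall survival.

The hazard of death at time ``t`` (days since diagnosis) is::

    h(t) = [lambda0 + delta_stage*1(cTNM>=III) + delta_linitis*1(linitis)]
           * b(t) * exp(beta_met * 1(t >= t_met))

with baseline shape ``b(t) = 1`` (constant / exponential), ``k t^(k-1)``
(Weibull) or ``e^(gamma t)`` (Gompertz).  Baseline covariates act additively
on the rate; the appearance of metastasis acts multiplicatively from the
observed metastasis time onward (a right-continuous time-dependent switch).
Survival is ``S(t) = exp(-HZ(t))`` with ``HZ`` the cumulative hazard.

The selected structure in the application is the constant family: the
published estimates carry no shape parameter, the baseline/stage/linitis
magnitudes are on the per-day rate scale and the metastasis coefficient is a
log hazard ratio.  Weibull and Gompertz exist for the model-comparison stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq, minimize

from . import _numdiff
from .cohort import CohortTable

__all__ = [
    "HazardParams",
    "SurvivalFitResult",
    "ParametricSurvivalModel",
    "KMCurve",
    "hazard_at",
    "cumulative_hazard",
    "survival_prob",
    "event_loglik",
    "fit_survival_model",
    "hazard_ratio",
    "simulate_event_time",
    "kaplan_meier",
    "km_at",
    "make_screen_fit",
    "survival_frame",
]

_FAMILIES = ("constant", "weibull", "gompertz")


@dataclass
class HazardParams:
    """Hazard parameters; rates are per day unless ``time_unit_days`` rescales.

    ``shape`` is the Weibull exponent k or the Gompertz log-slope gamma
    (ignored for the constant family).  ``delta_extra`` allows additional
    additive baseline increments for arbitrary boolean covariates (used by the
    covariate screen).
    """

    family: str = "constant"
    lambda0: float = 1e-4
    shape: float | None = None
    delta_stage: float = 0.0
    delta_linitis: float = 0.0
    beta_met: float = 0.0
    delta_extra: dict[str, float] = field(default_factory=dict)
    time_unit_days: float = 1.0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.family != "constant" and self.shape is None:
            raise ValueError(f"{self.family} family requires a shape parameter")
        if self.family == "weibull" and self.shape is not None and self.shape <= 0:
            raise ValueError("weibull shape must be positive")

    def base_rate(self, stage3, linitis, extra: Mapping | None = None) -> np.ndarray:
        rate = (
            self.lambda0
            + self.delta_stage * np.asarray(stage3, dtype=float)
            + self.delta_linitis * np.asarray(linitis, dtype=float)
        )
        if extra:
            for key, x in extra.items():
                rate = rate + self.delta_extra.get(key, 0.0) * np.asarray(x, dtype=float)
        if np.any(rate <= 0):
            raise ValueError("composite baseline hazard must be strictly positive")
        return rate


def _shape_factor(params: HazardParams, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float) / params.time_unit_days
    if params.family == "constant":
        return np.ones_like(t)
    if params.family == "weibull":
        k = params.shape
        with np.errstate(divide="ignore"):
            return k * np.power(np.maximum(t, 1e-300), k - 1.0)
    return np.exp(params.shape * t)  # gompertz


def hazard_at(
    params: HazardParams,
    t,
    stage3=False,
    linitis=False,
    t_met=None,
    extra: Mapping | None = None,
):
    """Instantaneous hazard (per day) at time ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    rate = params.base_rate(stage3, linitis, extra)
    h = rate * _shape_factor(params, t)
    if t_met is not None:
        h = h * np.exp(params.beta_met * (t >= np.asarray(t_met, dtype=float)))
    return h if h.ndim else float(h)


def _base_cumulative(params: HazardParams, t: np.ndarray) -> np.ndarray:
    """Integral of b(u) du from 0 to t (shape factor only, unit rate)."""
    t = np.asarray(t, dtype=float) / params.time_unit_days
    if params.family == "constant":
        out = t
    elif params.family == "weibull":
        out = np.power(t, params.shape)
    else:  # gompertz
        g = params.shape
        out = np.expm1(g * t) / g if abs(g) > 1e-12 else t
    return out * params.time_unit_days


def cumulative_hazard(
    params: HazardParams,
    t,
    stage3=False,
    linitis=False,
    t_met=None,
    extra: Mapping | None = None,
):
    """Cumulative hazard HZ(t) >= 0; piecewise across the metastasis switch."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    rate = params.base_rate(stage3, linitis, extra)
    if t_met is None:
        hz = rate * _base_cumulative(params, t)
    else:
        tm = np.asarray(t_met, dtype=float)
        pre = _base_cumulative(params, np.minimum(t, tm))
        post = _base_cumulative(params, np.maximum(t, tm)) - _base_cumulative(params, tm)
        post = np.where(t > tm, post, 0.0)
        hz = rate * (pre + np.exp(params.beta_met) * post)
    return hz if hz.ndim else float(hz)


def cumulative_hazard_quad(
    params: HazardParams, t: float, stage3=False, linitis=False, t_met=None,
    tol: float = 1e-10,
) -> float:
    """Adaptive-quadrature cumulative hazard (verification route)."""
    f = lambda u: hazard_at(params, u, stage3, linitis, t_met)
    points = [t_met] if (t_met is not None and 0 < t_met < t) else None
    val, _ = quad(f, 0.0, t, points=points, epsabs=tol, epsrel=tol, limit=200)
    return val


def survival_prob(params: HazardParams, t, stage3=False, linitis=False, t_met=None,
                  extra: Mapping | None = None):
    """S(t) = exp(-HZ(t))."""
    return np.exp(-np.asarray(cumulative_hazard(params, t, stage3, linitis, t_met, extra)))


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

def survival_frame(cohort: CohortTable, event_type: str = "death") -> pd.DataFrame:
    """One row per patient: event time/indicator, covariates, metastasis time.

    ``t_met`` is the *observed* metastasis time (NaN when metastasis was not
    observed before the event/censoring), entering the likelihood as the
    time-dependent switch.
    """
    ev = cohort.events
    target = ev[ev["event_type"] == event_type].set_index("patient_id")
    met = ev[ev["event_type"] == "metastasis"]
    met_obs = met[met["observed"].fillna(False).astype(bool)].set_index("patient_id")
    pats = cohort.patients.set_index("patient_id")
    df = pd.DataFrame(index=target.index)
    df["time_days"] = target["time_days"].astype(float)
    df["observed"] = target["observed"].astype(bool)
    df["stage3"] = (pats.loc[df.index, "ctnm_stage"] >= 3).fillna(False).astype(bool)
    df["linitis"] = pats.loc[df.index, "linitis"].fillna(False).astype(bool)
    df["t_met"] = met_obs["time_days"].reindex(df.index).astype(float)
    return df.reset_index()


def event_loglik(
    params: HazardParams,
    data: pd.DataFrame,
    extra_columns: Sequence[str] = (),
) -> float:
    """Log-likelihood of right-censored event records.

    ``data`` columns: ``time_days``, ``observed``, ``stage3``, ``linitis`` and
    optionally ``t_met`` (observed metastasis switch time, NaN = none) plus any
    boolean columns named in ``extra_columns``.
    """
    t = data["time_days"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("event times must be positive")
    obs = data["observed"].to_numpy(dtype=bool)
    stage3 = data.get("stage3", pd.Series(False, index=data.index)).to_numpy(dtype=bool)
    lin = data.get("linitis", pd.Series(False, index=data.index)).to_numpy(dtype=bool)
    extra = {c: data[c].to_numpy(dtype=float) for c in extra_columns}
    rate = params.base_rate(stage3, lin, extra)

    if "t_met" in data.columns:
        tm = data["t_met"].to_numpy(dtype=float)
    else:
        tm = np.full(t.shape, np.nan)
    has_met = np.isfinite(tm)

    base_t = _base_cumulative(params, t)
    hz = rate * base_t
    if has_met.any():
        tm_eff = np.where(has_met, tm, t)
        pre = _base_cumulative(params, np.minimum(t, tm_eff))
        post = np.maximum(base_t - pre, 0.0)
        hz = rate * (pre + np.exp(params.beta_met) * np.where(has_met, post, 0.0))

    h = rate * _shape_factor(params, t)
    if has_met.any():
        h = h * np.exp(params.beta_met * (has_met & (t >= tm)))
    with np.errstate(divide="ignore"):
        log_h = np.log(h)
    if np.any(~np.isfinite(log_h[obs])):
        return -np.inf
    return float(np.sum(log_h[obs]) - np.sum(hz))


@dataclass
class SurvivalFitResult:
    estimates: HazardParams
    ofv: float
    covariance: pd.DataFrame | None
    se: pd.Series | None
    rse_percent: pd.Series | None
    converged: bool
    n_subjects: int
    n_events: int
    free_names: list[str]
    message: str = ""
    model: "ParametricSurvivalModel | None" = None

    @property
    def params(self) -> HazardParams:
        return self.estimates

    def estimates_series(self) -> pd.Series:
        names, vec = _param_vector(self.estimates, self.model.extra_covariates
                                   if self.model else ())
        return pd.Series(vec, index=names)

    def wald_ci(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        if self.se is None:
            raise ValueError("covariance unavailable; no Wald intervals")
        est = self.estimates_series().loc[self.free_names]
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": est - z * self.se, "upper": est + z * self.se})

    def summary_frame(self) -> pd.DataFrame:
        est = self.estimates_series().loc[self.free_names]
        out = pd.DataFrame({"estimate": est})
        if self.se is not None:
            ci = self.wald_ci()
            out["se"] = self.se
            out["rse_percent"] = self.rse_percent
            out["lower95"] = ci["lower"]
            out["upper95"] = ci["upper"]
        return out

    def summary(self) -> str:
        lines = [
            f"Parametric survival model ({self.estimates.family} baseline hazard)",
            f"  subjects: {self.n_subjects}   events: {self.n_events}",
            f"  OFV (-2LL): {self.ofv:.4f}   converged: {self.converged}",
            "",
            self.summary_frame().to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_report_csv(self, path) -> None:
        self.summary_frame().reset_index(names="parameter").to_csv(path, index=False)


def _param_vector(params: HazardParams, extra_keys: Sequence[str]):
    names = ["lambda0"]
    vec = [params.lambda0]
    if params.family != "constant":
        names.append("shape")
        vec.append(params.shape)
    names += ["delta_stage", "delta_linitis", "beta_met"]
    vec += [params.delta_stage, params.delta_linitis, params.beta_met]
    for k in extra_keys:
        name = f"delta_{k}"
        if name in names:
            raise ValueError(
                f"extra covariate {k!r} collides with a built-in parameter; "
                "use the built-in stage3/linitis covariates instead"
            )
        names.append(name)
        vec.append(params.delta_extra.get(k, 0.0))
    return names, np.array(vec, dtype=float)


class ParametricSurvivalModel:
    """Parametric survival model bound to event data (fit with ``.fit()``).

    ``data`` may be a :class:`CohortTable` (the frame is derived with
    :func:`survival_frame`) or a prepared per-subject DataFrame.
    """

    def __init__(
        self,
        data: CohortTable | pd.DataFrame,
        family: str = "constant",
        event_type: str = "death",
        extra_covariates: Sequence[str] = (),
        use_metastasis_switch: bool = True,
    ):
        if isinstance(data, CohortTable):
            frame = survival_frame(data, event_type=event_type)
        else:
            frame = data.copy()
        if not use_metastasis_switch and "t_met" in frame.columns:
            frame = frame.drop(columns=["t_met"])
        if len(frame) == 0:
            raise ValueError("no event records for this event type")
        self.data = frame
        self.family = family
        self.extra_covariates = tuple(extra_covariates)
        self.n_events = int(frame["observed"].sum())

    def loglik(self, params: HazardParams) -> float:
        return event_loglik(params, self.data, self.extra_covariates)

    def ofv(self, params: HazardParams) -> float:
        return -2.0 * self.loglik(params)

    def fit(
        self,
        init: HazardParams | None = None,
        free: Sequence[str] | None = None,
        maxiter: int = 4000,
        ofv_tol: float = 1e-6,
        compute_covariance: bool = True,
    ) -> SurvivalFitResult:
        if self.n_events == 0:
            raise ValueError("cannot fit with zero observed events")
        if init is None:
            init = HazardParams(
                family=self.family,
                shape=1.0 if self.family == "weibull" else (0.0 if self.family == "gompertz" else None),
                delta_extra={k: 0.0 for k in self.extra_covariates},
            )
        init = replace(init, family=self.family)
        names, full0 = _param_vector(init, self.extra_covariates)
        free_names = list(names) if free is None else [n for n in names if n in set(free)]
        if free is not None and set(free) - set(names):
            raise ValueError(f"unknown parameter name(s) {sorted(set(free) - set(names))}")
        idx = [names.index(n) for n in free_names]
        # lambda0 (and weibull shape) are positive -> optimized on log scale;
        # additive rate increments are optimized in units of the initial
        # baseline rate so every internal coordinate is O(1) (keeps both the
        # simplex search and the finite-difference information well scaled)
        log_scale = {names.index("lambda0")}
        if self.family == "weibull":
            log_scale.add(names.index("shape"))
        rate_scale = max(init.lambda0, 1e-12)
        delta_idx = {
            names.index(n) for n in names
            if n.startswith("delta_") and n in free_names
        }

        def to_internal(full):
            v = full[idx].astype(float).copy()
            for j, i in enumerate(idx):
                if i in log_scale:
                    v[j] = math.log(max(full[i], 1e-300))
                elif i in delta_idx:
                    v[j] = full[i] / rate_scale
            return v

        def to_full(internal):
            full = full0.copy()
            for j, i in enumerate(idx):
                if i in log_scale:
                    full[i] = math.exp(internal[j])
                elif i in delta_idx:
                    full[i] = internal[j] * rate_scale
                else:
                    full[i] = internal[j]
            return full

        def make_params(full):
            d = dict(zip(names, full))
            return replace(
                init,
                lambda0=d["lambda0"],
                shape=d.get("shape", init.shape),
                delta_stage=d["delta_stage"],
                delta_linitis=d["delta_linitis"],
                beta_met=d["beta_met"],
                delta_extra={k: d[f"delta_{k}"] for k in self.extra_covariates},
            )

        def neg2ll(internal):
            try:
                p = make_params(to_full(internal))
                ll = self.loglik(p)
            except ValueError:
                return 1e12
            return -2.0 * ll if np.isfinite(ll) else 1e12

        if not free_names:
            return SurvivalFitResult(
                estimates=init, ofv=float(neg2ll(np.empty(0))), covariance=None,
                se=None, rse_percent=None, converged=True, free_names=[],
                n_subjects=len(self.data), n_events=self.n_events, model=self,
                message="all parameters fixed; OFV evaluated at init",
            )

        # Nelder-Mead with restarts: a fresh simplex from the previous
        # optimum guards against premature simplex collapse in >=4 dimensions
        x0 = to_internal(full0)
        best_x, best_f = x0, neg2ll(x0)
        success = True
        for _ in range(5):
            res = minimize(
                neg2ll, best_x, method="Nelder-Mead",
                options={"maxiter": maxiter, "maxfev": maxiter,
                         "fatol": ofv_tol, "xatol": 1e-6},
            )
            improved = best_f - res.fun
            if res.fun < best_f:
                best_x, best_f = np.asarray(res.x, dtype=float), float(res.fun)
            success = bool(res.success)
            if improved < max(10 * ofv_tol, 1e-4):
                break
        est = make_params(to_full(best_x))
        ofv = best_f

        cov = se = rse = None
        if compute_covariance:
            H = _numdiff.hessian(neg2ll, best_x)
            cov_internal = _numdiff.covariance_from_neg2ll_hessian(H)
            if cov_internal is not None:
                _, full = _param_vector(est, self.extra_covariates)
                jac = np.array(
                    [full[i] if i in log_scale
                     else (rate_scale if i in delta_idx else 1.0)
                     for i in idx]
                )
                cov_nat = cov_internal * np.outer(jac, jac)
                cov = pd.DataFrame(cov_nat, index=free_names, columns=free_names)
                se = pd.Series(np.sqrt(np.clip(np.diag(cov_nat), 0, None)),
                               index=free_names)
                est_free = pd.Series(full, index=names).loc[free_names]
                with np.errstate(divide="ignore"):
                    rse = 100.0 * se / est_free.abs()
        return SurvivalFitResult(
            estimates=est, ofv=ofv, covariance=cov, se=se, rse_percent=rse,
            converged=success, message=str(res.message),
            n_subjects=len(self.data), n_events=self.n_events,
            free_names=free_names, model=self,
        )


def fit_survival_model(
    cohort: CohortTable | pd.DataFrame,
    family: str = "constant",
    event_type: str = "death",
    init: HazardParams | None = None,
    free: Sequence[str] | None = None,
    extra_covariates: Sequence[str] = (),
    **options,
) -> SurvivalFitResult:
    """Functional wrapper around :class:`ParametricSurvivalModel`."""
    model = ParametricSurvivalModel(
        cohort, family=family, event_type=event_type, extra_covariates=extra_covariates
    )
    return model.fit(init=init, free=free, **options)


#: survival-frame columns handled by named HazardParams fields
_BUILTIN_COVARIATES = {"stage3": "delta_stage", "linitis": "delta_linitis"}


def make_screen_fit(
    data: CohortTable | pd.DataFrame,
    family: str = "constant",
    base_free: Sequence[str] = ("lambda0", "beta_met"),
):
    """Fit closure over covariate subsets, for the forward covariate screen.

    The returned callable ``fit(selected)`` frees one additive baseline-hazard
    increment per selected covariate: ``stage3`` and ``linitis`` map onto the
    built-in parameters, any other name onto an extra increment for the
    boolean column of that name in the survival frame.
    """
    frame = survival_frame(data) if isinstance(data, CohortTable) else data

    def fit(selected: Sequence[str]) -> SurvivalFitResult:
        extras = tuple(c for c in selected if c not in _BUILTIN_COVARIATES)
        model = ParametricSurvivalModel(frame, family=family,
                                        extra_covariates=extras)
        free = list(base_free) + [
            _BUILTIN_COVARIATES.get(c, f"delta_{c}") for c in selected
        ]
        return model.fit(free=free, compute_covariance=False)

    return fit


def hazard_ratio(params: HazardParams, effect: str) -> float:
    """Hazard ratio of a covariate at reference (otherwise baseline) settings."""
    if effect == "metastasis":
        return math.exp(params.beta_met)
    if effect == "stage3":
        return (params.lambda0 + params.delta_stage) / params.lambda0
    if effect == "linitis":
        return (params.lambda0 + params.delta_linitis) / params.lambda0
    if effect in params.delta_extra:
        return (params.lambda0 + params.delta_extra[effect]) / params.lambda0
    raise ValueError(f"unknown effect {effect!r}")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _invert_cumulative(params: HazardParams, rate: float, target: float,
                       t_met: float | None) -> float:
    """Solve HZ(T) = target for T (closed form for constant, root-find else)."""
    if params.family == "constant":
        if t_met is None or target <= rate * t_met:
            return target / rate
        return t_met + (target - rate * t_met) / (rate * math.exp(params.beta_met))
    f = lambda T: rate_cumhaz(params, rate, T, t_met) - target
    hi = 1.0
    while f(hi) < 0 and hi < 1e12:
        hi *= 4.0
    return brentq(f, 0.0, hi, xtol=1e-9, rtol=1e-12)


def rate_cumhaz(params: HazardParams, rate: float, t: float, t_met: float | None) -> float:
    if t_met is None:
        return rate * float(_base_cumulative(params, t))
    pre = float(_base_cumulative(params, min(t, t_met)))
    post = max(float(_base_cumulative(params, t)) - pre, 0.0)
    return rate * (pre + math.exp(params.beta_met) * post)


def simulate_event_time(
    params: HazardParams,
    stage3: bool = False,
    linitis: bool = False,
    t_met: float | None = None,
    max_follow_days: float = math.inf,
    rng: np.random.Generator | None = None,
) -> tuple[float, bool]:
    """Draw one event time by inverse-CDF sampling; returns (time, observed).

    Right-censored at ``max_follow_days`` (a zero follow-up yields an
    immediately censored record).
    """
    rng = rng if rng is not None else np.random.default_rng()
    rate = float(params.base_rate(stage3, linitis))
    target = rng.exponential(1.0)  # -log U
    T = _invert_cumulative(params, rate, target, t_met)
    if T >= max_follow_days:
        return float(max_follow_days), False
    return float(T), True


def simulate_event_times_constant(
    params: HazardParams,
    stage3: np.ndarray,
    linitis: np.ndarray,
    t_met: np.ndarray,
    max_follow_days: np.ndarray,
    rng: np.random.Generator,
    extra: Mapping | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized constant-family event-time simulation (NaN t_met = no switch)."""
    if params.family != "constant":
        raise ValueError("vectorized path supports the constant family only")
    rate = np.broadcast_to(
        np.asarray(params.base_rate(stage3, linitis, extra), dtype=float), stage3.shape
    )
    target = rng.exponential(1.0, size=stage3.shape)
    tm = np.where(np.isfinite(t_met), t_met, np.inf)
    pre_cap = rate * tm
    T = np.where(
        target <= pre_cap,
        target / rate,
        tm + (target - pre_cap) / (rate * math.exp(params.beta_met)),
    )
    observed = T < max_follow_days
    return np.where(observed, T, max_follow_days), observed


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct event times; ``survival`` the step values just
    after each; ``at_risk``/``events`` the risk-set size and number of events
    at each step.  At tied times events are processed before censorings.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "at_risk": self.at_risk, "events": self.events}
        )


def kaplan_meier(times, observed) -> KMCurve:
    """Kaplan-Meier estimator under right censoring."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(observed, dtype=bool)
    if t.size == 0:
        raise ValueError("empty stratum")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    event_times = np.unique(t[d])
    n = t.size
    surv, at_risk, events = [], [], []
    s = 1.0
    for et in event_times:
        r = int(np.sum(t >= et))  # censored ties stay in the risk set
        k = int(np.sum(d & (t == et)))
        s *= 1.0 - k / r
        surv.append(s)
        at_risk.append(r)
        events.append(k)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        events=np.asarray(events, dtype=int),
    )


def km_at(curve: KMCurve, t) -> np.ndarray | float:
    """Right-continuous step lookup of the KM curve; S(t) = 1 before the first event."""
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(curve.times, t, side="right") - 1
    out = np.where(idx >= 0, curve.survival[np.clip(idx, 0, None)], 1.0)
    return out if out.ndim else float(out)
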