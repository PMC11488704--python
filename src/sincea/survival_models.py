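"""Parametric survival models for right-censored pseudo-IPD.

Five families commonly used for extrapolating oncology trial endpoints are
supported: exponential, Weibull, log-normal, log-logistic and Gompertz.
Fitting maximizes the right-censored log-likelihood

    sum_{events} log f(t_i)  +  sum_{censored} log S(t_i)

with positive parameters optimized on the log scale and a small multi-start
to guard against local optima.  Model selection is by AIC with BIC and a
fixed family order as tie-breaks.

Parameterizations (time in months):

====================  =========================================  ==========
family                survivor function                          params
====================  =========================================  ==========
exponential           S(t) = exp(-lam * t)                       (lam,)
weibull               S(t) = exp(-(t/sigma)^k)                   (k, sigma)
lognormal             S(t) = 1 - Phi((ln t - mu)/sigma)          (mu, sigma)
loglogistic           S(t) = 1 / (1 + e^theta * t^kappa)         (theta, kappa)
gompertz              S(t) = exp(-(a/b) * (e^{b t} - 1))         (a, b)
====================  =========================================  ==========

The log-logistic form is the one used for the reference (chemotherapy) arm
of the cost-effectiveness model; its median survival time is exp(-theta/kappa).
Comparator arms are handled by the proportional-hazards power adjustment
``S_ref(t) ** HR``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "ParametricFit",
    "ArmSurvival",
    "FitError",
    "loglogistic_survival",
    "fit_family",
    "fit_all_families",
    "select_best",
    "hr_adjust",
    "fit_report",
]

#: Fixed family order; also the final tie-break in :func:`select_best`.
FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gompertz")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "lognormal": 2,
    "loglogistic": 2,
    "gompertz": 2,
}


class FitError(RuntimeError):
    """Raised when a parametric fit is infeasible or does not converge."""


def loglogistic_survival(theta: float, kappa: float, t):
    """Log-logistic survival probability ``1 / (1 + e^theta * t^kappa)``.

    Parameters
    ----------
    theta : float
        Unconstrained scale-like parameter on the log-odds scale.
    kappa : float
        Shape parameter, must be positive.
    t : float or array-like
        Time in months, nonnegative.

    Returns
    -------
    float or ndarray
        Survival probability in [0, 1]; exactly 1 at ``t == 0``.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    with np.errstate(divide="ignore"):
        # softplus keeps the tail stable: S = exp(-log(1 + e^{theta + kappa ln t}))
        z = np.where(t > 0, theta + kappa * np.log(np.where(t > 0, t, 1.0)), -np.inf)
    s = np.exp(-np.logaddexp(0.0, z))
    return float(s) if s.ndim == 0 else s


def hr_adjust(s_ref, hr: float):
    """Adjust a reference survival probability by a hazard ratio: ``s_ref ** hr``.

    Under proportional hazards S_arm(t) = S_ref(t)^HR; hr < 1 raises survival,
    hr > 1 lowers it.  Accepts scalars or arrays in [0, 1].
    """
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    s = np.asarray(s_ref, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("survival probabilities must lie in [0, 1]")
    out = s**hr
    return float(out) if out.ndim == 0 else out


# --- per-family log-density / log-survival -----------------------------------


def _logsf(family: str, params: Sequence[float], t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (lam,) = params
        return -lam * t
    if family == "weibull":
        k, sigma = params
        return -((t / sigma) ** k)
    if family == "lognormal":
        mu, sigma = params
        with np.errstate(divide="ignore"):
            logt = np.log(t)
        return stats.norm.logsf(logt, loc=mu, scale=sigma)
    if family == "loglogistic":
        theta, kappa = params
        with np.errstate(divide="ignore"):
            z = theta + kappa * np.log(t)
        return -np.logaddexp(0.0, z)
    if family == "gompertz":
        a, b = params
        bt = b * t
        # (e^{bt} - 1)/b -> t as b -> 0; expm1 keeps small-|b| accuracy
        small = np.abs(bt) < 1e-12
        grow = np.where(small, t, np.expm1(bt) / np.where(small, 1.0, b))
        return -a * grow
    raise ValueError(f"unknown family {family!r}")


def _logpdf(family: str, params: Sequence[float], t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    logt = np.log(t)
    if family == "exponential":
        (lam,) = params
        return math.log(lam) - lam * t
    if family == "weibull":
        k, sigma = params
        return math.log(k) - math.log(sigma) + (k - 1) * (logt - math.log(sigma)) - (t / sigma) ** k
    if family == "lognormal":
        mu, sigma = params
        return stats.norm.logpdf(logt, loc=mu, scale=sigma) - logt
    if family == "loglogistic":
        theta, kappa = params
        z = theta + kappa * logt
        return theta + math.log(kappa) + (kappa - 1) * logt - 2 * np.logaddexp(0.0, z)
    if family == "gompertz":
        a, b = params
        return math.log(a) + b * t + _logsf(family, params, t)
    raise ValueError(f"unknown family {family!r}")


# transform layout: which natural parameters are positive (fit on log scale)
_POSITIVE = {
    "exponential": (True,),
    "weibull": (True, True),
    "lognormal": (False, True),
    "loglogistic": (False, True),
    "gompertz": (True, False),
}


def _to_natural(family: str, raw: np.ndarray) -> np.ndarray:
    pos = _POSITIVE[family]
    return np.array([math.exp(r) if p else r for r, p in zip(raw, pos)])


def _to_raw(family: str, natural: Sequence[float]) -> np.ndarray:
    pos = _POSITIVE[family]
    return np.array([math.log(v) if p else v for v, p in zip(natural, pos)])


@dataclass(frozen=True)
class ParametricFit:
    """A fitted parametric survival family with information criteria.

    ``aic = 2k - 2 loglik`` and ``bic = k ln(n) - 2 loglik`` where ``k`` is
    the number of free parameters and ``n`` the number of records.
    """

    family: str
    params: tuple
    loglik: float
    aic: float
    bic: float
    n: int

    def survival(self, t):
        """Evaluate the fitted survivor function at times ``t`` (months)."""
        t = np.asarray(t, dtype=float)
        out = np.exp(_logsf(self.family, self.params, t))
        out = np.where(t == 0, 1.0, out)
        return float(out) if out.ndim == 0 else out

    def median(self) -> float:
        """Median survival time in months (numeric inversion of S)."""
        if self.family == "loglogistic":
            theta, kappa = self.params
            return math.exp(-theta / kappa)
        lo, hi = 1e-9, 1.0
        while self.survival(hi) > 0.5 and hi < 1e9:
            hi *= 2
        return float(optimize.brentq(lambda t: self.survival(t) - 0.5, lo, hi))


@dataclass(frozen=True)
class ArmSurvival:
    """Survival handles for one treatment arm of the Markov model.

    ``pfs`` and ``os`` are the *reference-arm* survivor functions; the
    hazard ratios are applied on evaluation via the power adjustment, so the
    reference arm itself uses ``hr_pfs = hr_os = 1``.
    """

    pfs: Callable[[np.ndarray], np.ndarray]
    os: Callable[[np.ndarray], np.ndarray]
    hr_pfs: float = 1.0
    hr_os: float = 1.0

    def __post_init__(self):
        if self.hr_pfs <= 0 or self.hr_os <= 0:
            raise ValueError("hazard ratios must be positive")

    def pfs_adjusted(self, t):
        return hr_adjust(self.pfs(np.asarray(t, dtype=float)), self.hr_pfs)

    def os_adjusted(self, t):
        return hr_adjust(self.os(np.asarray(t, dtype=float)), self.hr_os)


def _as_arrays(ipd) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ipd, pd.DataFrame):
        time = ipd["time_months"].to_numpy(dtype=float)
        event = ipd["event"].to_numpy(dtype=int)
    else:
        time, event = ipd
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
    if np.any(time <= 0):
        raise ValueError("all times must be positive")
    return time, event


def _starts(family: str, time: np.ndarray, event: np.ndarray) -> list[np.ndarray]:
    """Heuristic starting values (natural scale) plus jittered alternates."""
    total_time = time.sum()
    n_events = max(int(event.sum()), 1)
    lam0 = n_events / total_time
    ev_t = time[event == 1]
    med = float(np.median(ev_t)) if len(ev_t) else float(np.median(time))
    log_ev = np.log(ev_t) if len(ev_t) else np.log(time)
    mu0, sd0 = float(np.mean(log_ev)), max(float(np.std(log_ev)), 0.2)

    if family == "exponential":
        base = [np.array([lam0])]
    elif family == "weibull":
        base = [np.array([1.0, 1.0 / lam0]), np.array([1.5, med * 1.3])]
    elif family == "lognormal":
        base = [np.array([mu0, sd0])]
    elif family == "loglogistic":
        base = [np.array([-math.log(med), 1.0]), np.array([-1.5 * math.log(med), 1.5])]
    elif family == "gompertz":
        base = [np.array([lam0, 0.01]), np.array([lam0 * 0.5, 0.05])]
    else:
        raise ValueError(f"unknown family {family!r}")

    starts = [_to_raw(family, b) for b in base]
    rng = np.random.default_rng(0)
    while len(starts) < 3:
        starts.append(starts[0] + rng.normal(scale=0.3, size=starts[0].shape))
    return starts[:3]


def fit_family(ipd, family: str) -> ParametricFit:
    """Fit one parametric family to right-censored data by maximum likelihood.

    Parameters
    ----------
    ipd : DataFrame with columns ``time_months``/``event`` or (time, event) pair
        Times in months (> 0); event indicator 1 = event, 0 = censored.
    family : str
        One of :data:`FAMILIES`.

    Raises
    ------
    FitError
        If fewer than two events are present or the optimizer fails on
        every start.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    time, event = _as_arrays(ipd)
    n = len(time)
    if int(event.sum()) < 2:
        raise FitError(f"need at least 2 events to fit {family!r}, got {int(event.sum())}")
    t_ev, t_cen = time[event == 1], time[event == 0]

    def nll(raw: np.ndarray) -> float:
        natural = _to_natural(family, raw)
        if not np.all(np.isfinite(natural)):
            return np.inf
        with np.errstate(over="ignore", invalid="ignore"):
            ll = _logpdf(family, natural, t_ev).sum()
            if len(t_cen):
                ll += _logsf(family, natural, t_cen).sum()
        return np.inf if not np.isfinite(ll) else -ll

    best = None
    diagnostics = []
    for x0 in _starts(family, time, event):
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-8, "maxiter": 4000})
        diagnostics.append(res.message)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-12):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"optimizer failed for {family!r}: {diagnostics}")

    params = tuple(float(v) for v in _to_natural(family, best.x))
    loglik = -float(best.fun)
    k = _N_PARAMS[family]
    return ParametricFit(
        family=family,
        params=params,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(n) - 2 * loglik,
        n=n,
    )


def fit_all_families(ipd, families: Iterable[str] = FAMILIES) -> list[ParametricFit]:
    """Fit every requested family; families that fail to fit are skipped."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_family(ipd, fam))
        except FitError:
            continue
    if not fits:
        raise FitError("no family could be fitted")
    return fits


def select_best(fits: Sequence[ParametricFit]) -> ParametricFit:
    """Pick the best fit: minimal AIC, ties by minimal BIC, then family order."""
    if not fits:
        raise ValueError("empty fit list")
    return min(fits, key=lambda f: (f.aic, f.bic, FAMILIES.index(f.family)))


def fit_report(fits_by_endpoint: dict[str, Sequence[ParametricFit]]) -> pd.DataFrame:
    """Tabulate AIC/BIC per family and endpoint (goodness-of-fit report)."""
    rows = []
    for endpoint, fits in fits_by_endpoint.items():
        for f in fits:
            rows.append(
                {
                    "endpoint": endpoint,
                    "family": f.family,
                    "loglik": f.loglik,
                    "aic": f.aic,
                    "bic": f.bic,
                    "params": ";".join(f"{p:.6g}" for p in f.params),
                }
            )
    return pd.DataFrame(rows)
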