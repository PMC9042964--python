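"""Treatment efficacy: parametric survival fits to trial time-to-event data,
information-criterion model selection, per-cycle conditional fracture
incidence, time-dependent relative risks, and linear waning of the fracture
reduction benefit after treatment stops.

The bone-forming sequence and the antiresorptive comparator have different
benefit dynamics, so the sequence's RR versus its comparator is derived
cycle-by-cycle from survival curves fitted separately per arm; multiplying by
the comparator's constant placebo-anchored RR gives the per-cycle RR versus
placebo the Markov engine consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .config import FRACTURE_TYPES, N_TREATMENT_CYCLES

CYCLE_YEARS = 0.5

FAMILIES = (
    "exponential",
    "weibull",
    "gompertz",
    "log-logistic",
    "log-normal",
    "generalized-gamma",
)
# generalized-gamma is available on request but excluded from the default
# candidate set: with three parameters it rarely wins AIC/BIC at trial scale
# and its likelihood surface is flat enough to produce spurious optima.
DEFAULT_FAMILIES = (
    "exponential",
    "weibull",
    "gompertz",
    "log-logistic",
    "log-normal",
)

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gompertz": 2,
    "log-logistic": 2,
    "log-normal": 2,
    "generalized-gamma": 3,
}


class FitError(RuntimeError):
    pass


def _sf(family: str, theta: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Survival function for unconstrained parameter vector theta."""
    if family == "exponential":
        (mu,) = theta
        return lambda t: np.exp(-np.asarray(t, float) * np.exp(-mu))
    if family == "weibull":
        mu, logk = theta
        lam, k = np.exp(mu), np.exp(logk)
        return lambda t: np.exp(-((np.asarray(t, float) / lam) ** k))
    if family == "log-logistic":
        mu, logk = theta
        lam, k = np.exp(mu), np.exp(logk)
        return lambda t: 1.0 / (1.0 + (np.asarray(t, float) / lam) ** k)
    if family == "log-normal":
        mu, logs = theta
        s = np.exp(logs)
        return lambda t: stats.norm.sf((np.log(np.maximum(t, 1e-300)) - mu) / s)
    if family == "gompertz":
        loga, b = theta
        a = np.exp(loga)

        def S(t):
            t = np.asarray(t, float)
            if abs(b) < 1e-10:
                H = a * t
            else:
                H = a * np.expm1(b * t) / b
            return np.exp(-H)

        return S
    if family == "generalized-gamma":
        mu, logs, q = theta
        s = np.exp(logs)

        def S(t):  # Prentice log-time parameterisation
            t = np.asarray(t, float)
            w = (np.log(np.maximum(t, 1e-300)) - mu) / s
            if abs(q) < 1e-8:
                return stats.norm.sf(w)
            gam = q**-2
            u = gam * np.exp(q * w)
            if q > 0:
                return stats.gamma.sf(u, gam)
            return stats.gamma.cdf(u, gam)

        return S
    raise ValueError(f"unknown survival family {family!r}")


def _log_hazard(family: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = np.maximum(np.asarray(t, float), 1e-300)
    if family == "exponential":
        (mu,) = theta
        return np.full_like(t, -mu)
    if family == "weibull":
        mu, logk = theta
        k = np.exp(logk)
        return logk - mu + (k - 1.0) * (np.log(t) - mu)
    if family == "log-logistic":
        mu, logk = theta
        k = np.exp(logk)
        z = k * (np.log(t) - mu)
        return logk - np.log(t) + z - np.logaddexp(0.0, z)
    if family == "log-normal":
        mu, logs = theta
        s = np.exp(logs)
        w = (np.log(t) - mu) / s
        return stats.norm.logpdf(w) - logs - np.log(t) - stats.norm.logsf(w)
    if family == "gompertz":
        loga, b = theta
        return loga + b * t
    if family == "generalized-gamma":
        mu, logs, q = theta
        s = np.exp(logs)
        w = (np.log(t) - mu) / s
        if abs(q) < 1e-8:
            logf = stats.norm.logpdf(w) - logs - np.log(t)
        else:
            # Prentice log-time form: f_W(w) = |q| g^g exp(g(qw - e^{qw}))/Gamma(g)
            gam = q**-2
            logf = (
                np.log(abs(q))
                + gam * np.log(gam)
                + gam * (q * w - np.exp(q * w))
                - gammaln(gam)
                - logs
                - np.log(t)
            )
        S = _sf(family, theta)
        return logf - np.log(np.maximum(S(t), 1e-300))
    raise ValueError(f"unknown survival family {family!r}")


def _neg_log_lik(family: str, theta: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    S = _sf(family, theta)
    with np.errstate(all="ignore"):
        logS = np.log(np.maximum(S(t), 1e-300))
        ll = float(np.sum(logS))
        if e.any():
            ll += float(np.sum(_log_hazard(family, theta, t[e])))
    if not np.isfinite(ll):
        return 1e12
    return -ll


@dataclass
class SurvivalFit:
    """A maximum-likelihood parametric fit to right-censored event times."""

    family: str
    theta: np.ndarray  # unconstrained parameter vector (log-scale where positive)
    params: dict[str, float]
    intercept: float  # location on the log-time scale
    scale: float  # dispersion (family-specific meaning)
    log_likelihood: float
    n_params: int
    n: int
    n_events: int
    cov: Optional[np.ndarray] = None  # covariance of theta
    label: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n) - 2.0 * self.log_likelihood

    def survival(self, t) -> np.ndarray | float:
        out = _sf(self.family, self.theta)(t)
        return out if np.ndim(t) else float(out)

    def resample(self, rng: np.random.Generator) -> "SurvivalFit":
        """Draw a parameter vector from the asymptotic normal of the fit."""
        if self.cov is None:
            return self
        theta = rng.multivariate_normal(self.theta, self.cov)
        new = SurvivalFit(**{**self.__dict__})
        new.theta = theta
        return new


def _interpret(family: str, theta: np.ndarray) -> tuple[dict[str, float], float, float]:
    if family == "exponential":
        return {"rate": float(np.exp(-theta[0]))}, float(theta[0]), 1.0
    if family == "weibull":
        lam, k = float(np.exp(theta[0])), float(np.exp(theta[1]))
        return {"scale": lam, "shape": k}, float(theta[0]), 1.0 / k
    if family == "log-logistic":
        lam, k = float(np.exp(theta[0])), float(np.exp(theta[1]))
        return {"scale": lam, "shape": k}, float(theta[0]), 1.0 / k
    if family == "log-normal":
        return (
            {"mu": float(theta[0]), "sigma": float(np.exp(theta[1]))},
            float(theta[0]),
            float(np.exp(theta[1])),
        )
    if family == "gompertz":
        return (
            {"level": float(np.exp(theta[0])), "slope": float(theta[1])},
            float(theta[0]),
            float(theta[1]),
        )
    if family == "generalized-gamma":
        return (
            {"mu": float(theta[0]), "sigma": float(np.exp(theta[1])), "q": float(theta[2])},
            float(theta[0]),
            float(np.exp(theta[1])),
        )
    raise ValueError(family)


def _initial_theta(family: str, t: np.ndarray, e: np.ndarray) -> np.ndarray:
    # crude exponential-consistent start: mean time-to-event on log scale
    rate = max(e.sum(), 1) / max(t.sum(), 1e-12)
    mu0 = -np.log(rate)
    if family == "exponential":
        return np.array([mu0])
    if family == "gompertz":
        return np.array([np.log(rate), 0.01])
    if family == "generalized-gamma":
        return np.array([mu0, 0.0, 1.0])
    return np.array([mu0, 0.0])


def _numerical_cov(family, theta, t, e) -> Optional[np.ndarray]:
    k = theta.size
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    H = np.zeros((k, k))
    f0 = _neg_log_lik(family, theta, t, e)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = _neg_log_lik(family, theta + ei + ej, t, e)
            fpm = _neg_log_lik(family, theta + ei - ej, t, e)
            fmp = _neg_log_lik(family, theta - ei + ej, t, e)
            fmm = _neg_log_lik(family, theta - ei - ej, t, e)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        return None
    return cov


def fit_survival(
    records: pd.DataFrame,
    endpoint: str,
    arm: str,
    family: str,
) -> SurvivalFit:
    """Maximum-likelihood fit of one parametric family to one arm/endpoint.

    ``records`` is the trial long format (subject_id, arm, endpoint,
    time_years, event).  Fits are per arm, unadjusted, with right censoring.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r}")
    sub = records[(records["arm"] == arm) & (records["endpoint"] == endpoint)]
    if len(sub) == 0:
        raise FitError(f"no records for arm={arm!r}, endpoint={endpoint!r}")
    t = np.maximum(sub["time_years"].to_numpy(float), 1e-9)
    e = sub["event"].to_numpy(bool)
    if e.sum() == 0:
        raise FitError(f"no events for arm={arm!r}, endpoint={endpoint!r}")
    if np.unique(t[e]).size < 2:
        raise FitError("need at least 2 distinct event times")

    theta0 = _initial_theta(family, t, e)
    res = optimize.minimize(
        lambda th: _neg_log_lik(family, th, t, e),
        theta0,
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    res2 = optimize.minimize(
        lambda th: _neg_log_lik(family, th, t, e), res.x, method="BFGS"
    )
    theta = res2.x if res2.fun <= res.fun else res.x
    nll = min(res.fun, res2.fun)
    if not (res.success or res2.success) or not np.isfinite(nll):
        raise FitError(f"survival fit did not converge for family {family!r}")
    params, intercept, scale = _interpret(family, theta)
    return SurvivalFit(
        family=family,
        theta=np.asarray(theta, float),
        params=params,
        intercept=intercept,
        scale=scale,
        log_likelihood=-float(nll),
        n_params=_N_PARAMS[family],
        n=len(sub),
        n_events=int(e.sum()),
        cov=_numerical_cov(family, np.asarray(theta, float), t, e),
        label=f"{arm}/{endpoint}",
    )


def select_family(fits: Sequence[SurvivalFit], criterion: str = "AIC") -> SurvivalFit:
    """Pick the best fit by AIC, BIC, or the second-smallest AIC.

    Ties break toward fewer parameters, then lexicographic family name.
    """
    if not fits:
        raise ValueError("no fits supplied")
    if criterion in ("AIC", "BIC"):
        key = lambda f: (round(f.aic if criterion == "AIC" else f.bic, 10), f.n_params, f.family)
        return min(fits, key=key)
    if criterion == "second-AIC":
        if len(fits) < 2:
            raise ValueError("second-AIC selection needs at least 2 fits")
        ranked = sorted(fits, key=lambda f: (round(f.aic, 10), f.n_params, f.family))
        return ranked[1]
    raise ValueError(f"unknown selection criterion {criterion!r}")


def cycle_incidence(fit: SurvivalFit, cycle_index: int) -> float:
    """Conditional fracture probability in 6-month cycle j:
    (S(t_{j-1}) - S(t_j)) / S(t_{j-1})."""
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    t0 = (cycle_index - 1) * CYCLE_YEARS
    t1 = cycle_index * CYCLE_YEARS
    s0 = float(fit.survival(t0))
    if s0 <= 0.0:
        raise ZeroDivisionError(f"S({t0}) = 0; conditional incidence undefined")
    return (s0 - float(fit.survival(t1))) / s0


def cycle_rr(active_fit: SurvivalFit, comparator_fit: SurvivalFit, cycle_index: int) -> float:
    """Per-cycle RR of the active regimen versus its comparator."""
    denom = cycle_incidence(comparator_fit, cycle_index)
    if denom <= 0.0:
        raise ZeroDivisionError("comparator cycle incidence is 0; RR undefined")
    return cycle_incidence(active_fit, cycle_index) / denom


def compose_vs_placebo(
    rr_vs_active: Sequence[float], rr_active_vs_placebo: float
) -> np.ndarray:
    """Anchor a per-cycle RR-versus-active schedule to placebo by a constant
    active-versus-placebo RR (per-cycle product)."""
    sched = np.asarray(rr_vs_active, float)
    if np.any(sched <= 0) or rr_active_vs_placebo <= 0:
        raise ValueError("all RRs must be > 0")
    return sched * rr_active_vs_placebo


def offset_rr(base_rr: float, t_since_stop: float, offset_duration: float) -> float:
    """Effective RR while the fracture-reduction benefit wanes linearly.

    The risk *reduction* (1 - RR) declines linearly to 0 over the offset
    period: rr_eff = 1 - (1 - base_rr) * max(0, 1 - t/offset).
    """
    if offset_duration <= 0:
        raise ValueError("offset_duration must be > 0")
    if t_since_stop < 0:
        raise ValueError("t_since_stop must be >= 0")
    frac = max(0.0, 1.0 - t_since_stop / offset_duration)
    return 1.0 - (1.0 - base_rr) * frac


def schedule_from_trial(
    records: pd.DataFrame,
    active_arm: str = "active",
    comparator_arm: str = "comparator",
    endpoints: Sequence[str] = ("hip", "other"),
    families: Sequence[str] = DEFAULT_FAMILIES,
    criterion: str = "AIC",
    n_cycles: int = N_TREATMENT_CYCLES,
) -> tuple[dict[str, list[float]], dict[str, dict[str, SurvivalFit]]]:
    """Derive the per-cycle RR-versus-comparator schedule from trial data.

    Fits every candidate family separately per arm and endpoint, selects by
    the given information criterion, and takes per-cycle incidence ratios.
    Returns (schedule, selected fits keyed by endpoint then arm).
    """
    schedule: dict[str, list[float]] = {}
    selected: dict[str, dict[str, SurvivalFit]] = {}
    for ep in endpoints:
        sel = {}
        for arm in (active_arm, comparator_arm):
            fits = []
            for fam in families:
                try:
                    fits.append(fit_survival(records, ep, arm, fam))
                except FitError as exc:
                    warnings.warn(f"{fam} fit failed for {arm}/{ep}: {exc}")
            if not fits:
                raise FitError(f"no family converged for {arm}/{ep}")
            sel[arm] = select_family(fits, criterion)
        selected[ep] = sel
        schedule[ep] = [
            cycle_rr(sel[active_arm], sel[comparator_arm], j)
            for j in range(1, n_cycles + 1)
        ]
    return schedule, selected
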