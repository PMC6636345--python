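"""Kaplan-Meier product-limit estimation and the Cox proportional-hazards
model, implemented on the partial likelihood (no delegation).

Cox fitting is Newton-Raphson with step-halving on the log partial
likelihood, Efron tie correction by default (EMR day granularity guarantees
ties) with Breslow retained for cross-checks.  Efron and Breslow coincide
exactly when no event times are tied.  Wald z / CIs throughout, matching the
HR (CI) presentation convention; a coefficient with se > 2 sets an
instability flag on the fit rather than suppressing output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, ConvergenceError, RankDeficiencyError

_LL_TOL = 1e-9
_MAX_ITER = 50


@dataclass
class KMCurve:
    event_times: np.ndarray  # distinct event times, ascending
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) at each event time
    greenwood_se: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self, group: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "group": group,
            "time": self.event_times,
            "n_risk": self.n_risk,
            "n_event": self.n_events,
            "survival": self.survival,
            "se": self.greenwood_se,
        })


def km(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Product-limit estimate with Greenwood standard errors.

    Censored-only times reduce the risk set but contribute no step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ConfigError("km requires at least one subject")
    if np.any(times <= 0):
        raise ConfigError("km requires strictly positive times")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)

    out_t, out_n, out_d, out_s, out_se = [], [], [], [], []
    s = 1.0
    gw = 0.0  # running sum d_i / (n_i (n_i - d_i))
    i = 0
    while i < n:
        t = times[i]
        j = i
        d = 0
        while j < n and times[j] == t:
            d += events[j]
            j += 1
        n_risk = n - i
        if d > 0:
            s *= 1.0 - d / n_risk
            if n_risk > d:
                gw += d / (n_risk * (n_risk - d))
                se = s * np.sqrt(gw)
            else:
                se = 0.0  # S has hit 0; Greenwood term degenerates
            out_t.append(t)
            out_n.append(n_risk)
            out_d.append(d)
            out_s.append(s)
            out_se.append(se)
        i = j
    return KMCurve(
        event_times=np.array(out_t),
        n_risk=np.array(out_n, dtype=int),
        n_events=np.array(out_d, dtype=int),
        survival=np.array(out_s),
        greenwood_se=np.array(out_se),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    covariates: list[str]
    coefficients: np.ndarray
    se: np.ndarray
    hazard_ratios: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    ci95: list[tuple[float, float]]  # exp(beta +/- 1.96 se)
    ties_method: str
    converged: bool
    n_iterations: int
    log_partial_likelihood: float
    unstable: bool  # any se > 2: estimate reported but flagged meaningless

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariates,
            "coef": self.coefficients,
            "hazard_ratio": self.hazard_ratios,
            "se": self.se,
            "z": self.wald_z,
            "p_value": self.p_values,
            "ci95_lower": [c[0] for c in self.ci95],
            "ci95_upper": [c[1] for c in self.ci95],
            "unstable": self.unstable,
        })


def _cox_ll_grad_info(beta, times, events, X, ties):
    """Log partial likelihood, score vector, and observed information."""
    n, p = X.shape
    eta = X @ beta
    # the partial likelihood is invariant to a constant shift of eta (event
    # terms and risk-set denominators shift identically), so shift for
    # overflow safety
    eta = eta - eta.max()
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)

    # suffix sums over subjects ordered by ascending time: position k holds
    # the risk-set aggregate for any event time equal to times[k]
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    shift_const = 0.0  # re-add the eta shift in the event terms
    i = 0
    while i < n:
        t = times[i]
        j = i
        while j < n and times[j] == t:
            j += 1
        ev = np.flatnonzero(events[i:j]) + i
        d = len(ev)
        if d > 0:
            ll += float(eta[ev].sum())
            grad += X[ev].sum(axis=0)
            s0, s1, s2 = S0[i], S1[i], S2[i]
            if ties == "efron" and d > 1:
                d0 = w[ev].sum()
                d1 = wX[ev].sum(axis=0)
                d2 = wXX[ev].sum(axis=0)
                for l in range(d):
                    f = l / d
                    p0 = s0 - f * d0
                    p1 = s1 - f * d1
                    p2 = s2 - f * d2
                    ll -= np.log(p0)
                    grad -= p1 / p0
                    info += p2 / p0 - np.outer(p1, p1) / p0**2
            else:  # breslow, or untied (methods coincide)
                ll -= d * np.log(s0)
                grad -= d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        i = j
    return ll, grad, info


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time_days",
    event_col: str = "event",
    ties: str = "efron",
) -> CoxFit:
    """Fit the Cox model by Newton-Raphson on the partial likelihood.

    Raises ConvergenceError on monotone likelihood (a covariate that
    perfectly separates events drives its coefficient to infinity).
    """
    if ties not in ("efron", "breslow"):
        raise ConfigError(f"unknown ties method {ties!r}")
    if not covariates:
        raise ConfigError("cox_fit requires at least one covariate")
    times = data[time_col].to_numpy(dtype=float)
    events = data[event_col].to_numpy(dtype=int)
    if np.any(times <= 0):
        raise ConfigError("cox_fit requires strictly positive times")
    if events.sum() < 1:
        raise ConfigError("cox_fit requires at least one event")
    X = data[list(covariates)].to_numpy(dtype=float)

    order = np.argsort(times, kind="stable")
    times, events, X = times[order], events[order], X[order]
    # center columns for numeric stability; the partial likelihood and beta
    # are invariant to column shifts
    X = X - X.mean(axis=0)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(covariates)

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _cox_ll_grad_info(beta, times, events, X, ties)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular information matrix") from None
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _cox_ll_grad_info(cand, times, events, X, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        delta = ll_new - ll
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        # |beta| > 15 is a hazard ratio beyond 3e6: the likelihood is monotone
        # (a covariate perfectly separates events) and the MLE sits at
        # infinity; the log-likelihood plateau would otherwise stop Newton at
        # an arbitrary large value
        if np.max(np.abs(beta)) > 15.0:
            raise ConvergenceError(
                "diverging coefficient (monotone partial likelihood)"
            )
        if abs(delta) <= _LL_TOL:
            converged = True
            break

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ConvergenceError("information matrix not invertible at optimum") from None
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * (1.0 - norm.cdf(np.abs(z)))
    with np.errstate(over="ignore"):  # unstable fits can push bounds to inf
        ci = [(float(np.exp(b - 1.96 * s)), float(np.exp(b + 1.96 * s)))
              for b, s in zip(beta, se)]
    return CoxFit(
        covariates=list(covariates),
        coefficients=beta,
        se=se,
        hazard_ratios=np.exp(beta),
        wald_z=z,
        p_values=pvals,
        ci95=ci,
        ties_method=ties,
        converged=converged,
        n_iterations=it,
        log_partial_likelihood=ll,
        unstable=bool(np.any(se > 2.0)),
    )


def summarize(
    fits: list[dict],
    reference_group: str,
) -> pd.DataFrame:
    """Hazard-ratio results table with the reference group printed as HR 1.

    ``fits`` items: {mode, outcome, group, events_reference, events_treated,
    fit: CoxFit, treatment_covariate}.  Layout mirrors the published table:
    (mode, group, outcome, events, hazard_ratio, p_value, ci95).
    """
    rows = []
    for item in fits:
        fit: CoxFit = item["fit"]
        k = fit.covariates.index(item.get("treatment_covariate", "group"))
        rows.append({
            "mode": item["mode"],
            "group": reference_group,
            "outcome": item["outcome"],
            "events": item["events_reference"],
            "hazard_ratio": 1.0,
            "p_value": "",
            "ci95": "",
            "unstable": "",
        })
        lo, hi = fit.ci95[k]
        rows.append({
            "mode": item["mode"],
            "group": item["group"],
            "outcome": item["outcome"],
            "events": item["events_treated"],
            "hazard_ratio": round(float(fit.hazard_ratios[k]), 2),
            "p_value": round(float(fit.p_values[k]), 2),
            "ci95": f"{lo:.2f}-{hi:.2f}",
            "unstable": bool(fit.unstable),
        })
    return pd.DataFrame(
        rows,
        columns=["mode", "group", "outcome", "events", "hazard_ratio",
                 "p_value", "ci95", "unstable"],
    )
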