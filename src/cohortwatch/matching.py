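"""Propensity-score estimation, greedy caliper matching, balance diagnostics.

The logistic regression is implemented here (iteratively reweighted least
squares with step-halving), not delegated, so its convergence and failure
behavior are fully specified.  Matching is greedy 1:1 nearest-neighbor
without replacement, processed in a seed-derived random order with
deterministic tie-breaking, so identical seeds reproduce identical pairs on
any platform and any input row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ConfigError, RankDeficiencyError, SeparationError

_GRAD_TOL = 1e-8
_LL_TOL = 1e-10
_MAX_ITER = 100


@dataclass
class PropensityFit:
    coefficients: dict[str, float]  # intercept + per-covariate, log-odds scale
    scores: pd.Series  # probability in (0,1), indexed by patient_id
    converged: bool
    n_iterations: int
    log_likelihood: float


@dataclass
class MatchedSet:
    pairs: list[tuple[str, str, float]]  # (treated_id, control_id, distance)
    caliper_used: float  # on the matching scale
    scale: str
    unmatched_treated: list[str]
    unmatched_control: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["treated_id", "control_id", "distance"]
        )


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise RankDeficiencyError(bad)


def fit_logistic(
    rows: pd.DataFrame,
    covariates: list[str],
    outcome: str = "group",
) -> PropensityFit:
    """Maximum-likelihood logistic fit of ``outcome`` on ``covariates``.

    IRLS (Newton) with step-halving; converges when the largest score-equation
    component is <= 1e-8 or the relative log-likelihood change is <= 1e-10.
    Raises SeparationError on perfect separation and RankDeficiencyError
    naming the collinear columns.
    """
    y = rows[outcome].to_numpy(dtype=float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ConfigError("fit_logistic requires at least 2 subjects per group")
    names = ["intercept"] + list(covariates)
    X = np.column_stack(
        [np.ones(len(rows))] + [rows[c].to_numpy(dtype=float) for c in covariates]
    )
    _check_rank(X, names)

    beta = np.zeros(X.shape[1])
    ll = _log_likelihood(y, X @ beta)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise SeparationError("singular information matrix (separation)") from None

        # step-halving to guarantee likelihood ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _log_likelihood(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, ll_prev, ll = cand, ll, ll_new

        if np.max(np.abs(beta)) > 100.0:
            raise SeparationError("diverging coefficients (perfect separation)")
        if np.max(np.abs(grad)) <= _GRAD_TOL:
            converged = True
            break
        if abs(ll - ll_prev) <= _LL_TOL * (abs(ll_prev) + 1e-12):
            converged = True
            break

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    if np.any(p <= 1e-10) or np.any(p >= 1.0 - 1e-10):
        raise SeparationError("fitted probabilities at machine 0/1 (separation)")

    scores = pd.Series(p, index=rows["patient_id"].to_numpy(), name="propensity")
    return PropensityFit(
        coefficients=dict(zip(names, beta)),
        scores=scores,
        converged=converged,
        n_iterations=it,
        log_likelihood=ll,
    )


def match(
    scores: pd.Series,
    groups: pd.Series,
    caliper: float,
    caliper_scale: str = "logit_sd",
    seed: int = 0,
) -> MatchedSet:
    """Greedy 1:1 nearest-neighbor caliper matching without replacement.

    ``scores`` and ``groups`` are indexed by patient_id; ``groups`` is the
    0/1 treatment indicator.  Treated subjects are processed in a random
    order drawn from ``seed``; each takes the nearest available control
    within the caliper, with ties broken by smallest control patient_id.
    On the ``logit_sd`` scale, distances are measured between logit scores
    and the caliper is ``caliper * SD(logit scores, pooled)``.
    """
    if caliper <= 0:
        raise ConfigError(f"caliper must be positive, got {caliper}")
    if caliper_scale not in ("logit_sd", "raw"):
        raise ConfigError(f"unknown caliper_scale {caliper_scale!r}")

    s = scores.astype(float)
    if caliper_scale == "logit_sd":
        vals = np.log(s / (1.0 - s))
        caliper_used = caliper * float(np.std(vals, ddof=1))
    else:
        vals = s.to_numpy(dtype=float)
        caliper_used = caliper
    vals = pd.Series(np.asarray(vals, dtype=float), index=s.index)

    treated_ids = sorted(groups.index[groups == 1])
    control_ids = sorted(groups.index[groups == 0])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(treated_ids))

    avail_ids = np.array(control_ids, dtype=object)
    avail_vals = vals.loc[control_ids].to_numpy()
    available = np.ones(len(control_ids), dtype=bool)

    pairs: list[tuple[str, str, float]] = []
    unmatched_treated: list[str] = []
    for i in order:
        tid = treated_ids[i]
        tval = vals.loc[tid]
        if not available.any():
            unmatched_treated.append(tid)
            continue
        dist = np.abs(avail_vals - tval)
        dist[~available] = np.inf
        best = float(dist.min())
        if best > caliper_used:
            unmatched_treated.append(tid)
            continue
        # ties broken by smallest control patient_id; ids are pre-sorted
        j = int(np.flatnonzero(dist == best)[0])
        available[j] = False
        pairs.append((tid, str(avail_ids[j]), best))

    assert all(d <= caliper_used for _, _, d in pairs)
    pairs.sort(key=lambda p: p[0])
    return MatchedSet(
        pairs=pairs,
        caliper_used=caliper_used,
        scale=caliper_scale,
        unmatched_treated=sorted(unmatched_treated),
        unmatched_control=[str(c) for c, ok in zip(avail_ids, available) if ok],
    )


def _smd(x1: np.ndarray, x0: np.ndarray) -> float:
    binary = set(np.unique(np.concatenate([x1, x0]))) <= {0.0, 1.0}
    m1, m0 = float(np.mean(x1)), float(np.mean(x0))
    if binary:
        pooled = (m1 * (1 - m1) + m0 * (1 - m0)) / 2.0
    else:
        v1 = float(np.var(x1, ddof=1)) if len(x1) > 1 else 0.0
        v0 = float(np.var(x0, ddof=1)) if len(x0) > 1 else 0.0
        pooled = (v1 + v0) / 2.0
    if pooled <= 0.0:
        return 0.0 if m1 == m0 else float("inf")
    return abs(m1 - m0) / np.sqrt(pooled)


def balance(
    rows: pd.DataFrame,
    covariates: list[str],
    matched: MatchedSet | None = None,
    smd_threshold: float = 0.1,
) -> pd.DataFrame:
    """Before/after standardized-mean-difference balance table.

    Returns one row per covariate per phase ("before", and "after" when a
    matched set is supplied), with columns mean_treated, mean_control, smd,
    balanced (|SMD| below the threshold).
    """
    out = []

    def phase_rows(frame: pd.DataFrame, phase: str) -> None:
        g1 = frame[frame["group"] == 1]
        g0 = frame[frame["group"] == 0]
        for cov in covariates:
            x1 = g1[cov].to_numpy(dtype=float)
            x0 = g0[cov].to_numpy(dtype=float)
            smd = _smd(x1, x0)
            out.append({
                "covariate": cov,
                "phase": phase,
                "mean_treated": float(np.mean(x1)),
                "mean_control": float(np.mean(x0)),
                "smd": smd,
                "balanced": bool(smd < smd_threshold),
            })

    phase_rows(rows, "before")
    if matched is not None:
        keep = {pid for t, c, _ in matched.pairs for pid in (t, c)}
        phase_rows(rows[rows["patient_id"].isin(keep)], "after")
    return pd.DataFrame(
        out, columns=["covariate", "phase", "mean_treated", "mean_control", "smd", "balanced"]
    )
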