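"""Survival analysis kernels: Kaplan-Meier, k-group log-rank, Cox
proportional hazards (Newton-Raphson on the partial likelihood with Efron or
Breslow tie handling), and score cut-point selection.

These are written from the estimating equations rather than delegating to a
survival library, because the univariate Cox screen and the log-rank tests
are load-bearing steps of the pipeline; an established implementation serves
as the independent oracle in the test suite instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvivalCurve:
    """Product-limit estimate: event times, risk/event counts, S(t)."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    median: float | None

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class CoxResult:
    """Per-covariate partial-likelihood estimates."""

    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    ties: str
    converged: bool
    iterations: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p_value(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "hr": self.hr, "se": self.se,
                             "z": self.z, "p": self.p_value}, index=self.names)


def _check_times(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival data")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return times, events


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    The median is the smallest observed time with S(t) <= 0.5, or None if
    the curve never reaches 0.5.
    """
    times, events = _check_times(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    uniq = np.unique(t_sorted)
    n = times.size
    at_risk, d, surv = [], [], []
    s = 1.0
    for t in uniq:
        r = int((t_sorted >= t).sum())
        dt = int(e_sorted[t_sorted == t].sum())
        s *= 1.0 - dt / r
        at_risk.append(r)
        d.append(dt)
        surv.append(s)
    surv = np.array(surv)
    median = None
    hit = np.nonzero(surv <= 0.5)[0]
    if hit.size:
        median = float(uniq[hit[0]])
    return SurvivalCurve(uniq, np.array(at_risk), np.array(d), surv, median)


def logrank_test(times, events, groups) -> LogRankResult:
    """k-group log-rank test (observed vs expected events, hypergeometric
    variance), chi-square with k-1 degrees of freedom."""
    times, events = _check_times(times, events)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank needs at least 2 groups")
    masks = np.stack([groups == g for g in labels])  # k x n

    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & (events == 1)).sum())
        n_g = masks[:, at_risk].sum(axis=1).astype(float)
        d_g = masks[:, (times == t) & (events == 1)].sum(axis=1).astype(float)
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            factor = d_t * (n_t - d_t) / (n_t - 1.0)
            p_g = n_g / n_t
            V += factor * (np.diag(p_g) - np.outer(p_g, p_g))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, k - 1))
    return LogRankResult(stat, k - 1, p)


def cox_fit(times, events, covariates, names: list[str] | None = None,
            ties: str = "efron", max_iter: int = 50, tol: float = 1e-9,
            beta_cap: float = 20.0) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson.

    ``covariates`` is (n,) or (n, p).  Efron tie correction by default;
    convergence when the max absolute score falls below ``tol``.  Monotone
    likelihoods (perfect separation) are flagged as non-converged with the
    coefficient capped at ``beta_cap``.
    """
    times, events = _check_times(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if events.sum() == 0:
        raise ValueError("no events in the data")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    order = np.argsort(times, kind="stable")
    t_s, e_s, X_s = times[order], events[order], X[order]
    event_times = np.unique(t_s[e_s == 1])

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X_s @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        score = np.zeros(p)
        info = np.zeros((p, p))
        for t in event_times:
            risk = t_s >= t
            dead = (t_s == t) & (e_s == 1)
            d = int(dead.sum())
            xd = X_s[dead]
            sum_xd = xd.sum(axis=0)
            wr = w[risk]
            Xr = X_s[risk]
            s0 = wr.sum()
            s1 = wr @ Xr
            s2 = Xr.T @ (wr[:, None] * Xr)
            if ties == "breslow" or d == 1:
                mean = s1 / s0
                score += sum_xd - d * mean
                info += d * (s2 / s0 - np.outer(mean, mean))
            else:  # efron
                wd = w[dead]
                s0d = wd.sum()
                s1d = wd @ xd
                s2d = xd.T @ (wd[:, None] * xd)
                for l in range(d):
                    f = l / d
                    s0l = s0 - f * s0d
                    s1l = s1 - f * s1d
                    s2l = s2 - f * s2d
                    mean = s1l / s0l
                    score += -mean
                    info += s2l / s0l - np.outer(mean, mean)
                score += sum_xd
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(beta)) > beta_cap:
            beta = np.clip(beta, -beta_cap, beta_cap)
            break

    # observed information at the final beta for standard errors
    eta = np.clip(X_s @ beta, -500, 500)
    w = np.exp(eta)
    info = np.zeros((p, p))
    for t in event_times:
        risk = t_s >= t
        dead = (t_s == t) & (e_s == 1)
        d = int(dead.sum())
        wr = w[risk]
        Xr = X_s[risk]
        s0 = wr.sum()
        s1 = wr @ Xr
        s2 = Xr.T @ (wr[:, None] * Xr)
        if ties == "breslow" or d == 1:
            mean = s1 / s0
            info += d * (s2 / s0 - np.outer(mean, mean))
        else:
            wd = w[dead]
            xd = X_s[dead]
            s0d, s1d = wd.sum(), wd @ xd
            s2d = xd.T @ (wd[:, None] * xd)
            for l in range(d):
                f = l / d
                s0l = s0 - f * s0d
                mean = (s1 - f * s1d) / s0l
                info += (s2 - f * s2d) / s0l - np.outer(mean, mean)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return CoxResult(beta, se, names, ties, converged, it)


def cox_screen(expr_values: pd.DataFrame, times, events,
               p_threshold: float = 0.01) -> pd.DataFrame:
    """Univariate Cox per gene row; returns beta/HR/p with a significance flag."""
    rows = []
    for gene, x in expr_values.iterrows():
        xv = x.to_numpy(dtype=float)
        if xv.std() == 0:
            rows.append((gene, np.nan, np.nan, np.nan, 1.0, False))
            continue
        res = cox_fit(times, events, (xv - xv.mean()) / xv.std())
        rows.append((gene, float(res.beta[0]), float(res.hr[0]), float(res.se[0]),
                     float(res.p_value[0]), bool(res.p_value[0] < p_threshold)))
    out = pd.DataFrame(rows, columns=["gene", "beta", "hr", "se", "p", "significant"])
    return out.set_index("gene")


def choose_cutpoint(score, times, events, method: str = "median",
                    min_prop: float = 0.1) -> tuple[float, np.ndarray]:
    """Split a continuous score into low/high groups.

    ``median`` thresholds at the sample median; ``maxstat`` maximizes the
    two-group log-rank statistic over candidate splits that keep at least
    ``min_prop`` of samples on each side.  Returns (threshold, labels) with
    labels in {"low", "high"}; scores > threshold are "high".
    """
    score = np.asarray(score, dtype=float)
    times, events = _check_times(times, events)
    if score.std() == 0:
        raise ValueError("constant score; no cutpoint exists")
    if method == "median":
        thr = float(np.median(score))
    elif method == "maxstat":
        if score.size < 20:
            raise ValueError("maxstat needs n >= 20")
        lo_q, hi_q = np.quantile(score, [min_prop, 1.0 - min_prop])
        cands = np.unique(score[(score >= lo_q) & (score <= hi_q)])
        best_stat, thr = -np.inf, float(np.median(score))
        for c in cands[:-1] if cands.size > 1 else cands:
            grp = np.where(score > c, "high", "low")
            if len(np.unique(grp)) < 2:
                continue
            s = logrank_test(times, events, grp).statistic
            if s > best_stat:
                best_stat, thr = s, float(c)
    else:
        raise ValueError(f"unknown cutpoint method {method!r}")
    labels = np.where(score > thr, "high", "low")
    if len(np.unique(labels)) < 2:
        raise ValueError("cutpoint produced a single group")
    return thr, labels
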