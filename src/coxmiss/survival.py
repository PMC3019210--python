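"""Cox proportional hazards fitting and prognostic performance measures.

The partial likelihood is maximised by Newton-Raphson with Efron's tie
correction (generated times are continuous but bootstrap duplication creates
ties).  The fitter is written against a plain design matrix so the same core
serves the 8-covariate prognostic model and the univariate fit inside the
prognostic-separation statistic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .population import COVARIATES

__all__ = [
    "CoxFitResult",
    "cox_fit_matrix",
    "fit_cox",
    "nagelkerke_r2",
    "royston_d",
    "predicted_survival",
    "breslow_cumhaz",
    "nelson_aalen_at",
]

KAPPA = math.sqrt(8.0 / math.pi)


@dataclass
class CoxFitResult:
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    loglik_null: float
    loglik: float
    linear_predictor: np.ndarray
    n: int
    n_events: int
    converged: bool
    names: tuple[str, ...]
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    def z(self) -> np.ndarray:
        return self.beta / self.se

    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z()))

    def confint(self, level: float = 0.95) -> np.ndarray:
        q = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.beta - q * self.se, self.beta + q * self.se])

    def to_json(self) -> str:
        return json.dumps(
            {
                "names": list(self.names),
                "beta": self.beta.tolist(),
                "se": self.se.tolist(),
                "vcov": self.vcov.tolist(),
                "loglik_null": self.loglik_null,
                "loglik": self.loglik,
                "n": self.n,
                "n_events": self.n_events,
                "converged": self.converged,
            }
        )


def _efron_loglik_grad_hess(
    x: np.ndarray, beta: np.ndarray, starts: np.ndarray, stops: np.ndarray,
    event_sorted: np.ndarray, d_per_group: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron partial log-likelihood and derivatives.

    ``x`` is sorted by descending time; (starts, stops) delimit tie groups in
    that ordering (rows sharing one time).  The risk set of a group is rows
    [0, stop).  Groups with a single event (the vast majority) are handled in
    one vectorised pass; multi-event tie groups get the Efron inner loop.
    """
    n, p = x.shape
    eta = x @ beta
    eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]
    s0 = np.cumsum(w)
    s1 = np.cumsum(wx, axis=0)
    s2 = np.cumsum(wxx, axis=0)

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    single = d_per_group == 1
    if single.any():
        ends = stops[single] - 1
        # the event row inside each single-event group
        rows = np.array(
            [a + int(np.argmax(event_sorted[a:b])) for a, b in zip(starts[single], stops[single])]
        )
        r0 = s0[ends]
        m1 = s1[ends] / r0[:, None]
        loglik += float(eta[rows].sum() - np.log(r0).sum())
        grad += x[rows].sum(axis=0) - m1.sum(axis=0)
        hess -= np.einsum("g,gij->ij", 1.0 / r0, s2[ends]) - np.einsum(
            "gi,gj->ij", m1, m1
        )

    for a, b in zip(starts[d_per_group > 1], stops[d_per_group > 1]):
        ev = event_sorted[a:b].astype(bool)
        rows = np.arange(a, b)[ev]
        d = rows.size
        r0, r1, r2 = s0[b - 1], s1[b - 1], s2[b - 1]
        t0 = w[rows].sum()
        t1 = wx[rows].sum(axis=0)
        t2 = wxx[rows].sum(axis=0)
        loglik += float(eta[rows].sum())
        for f in np.arange(d) / d:
            den = r0 - f * t0
            m1 = (r1 - f * t1) / den
            loglik -= math.log(den)
            grad -= m1
            hess -= (r2 - f * t2) / den - np.outer(m1, m1)
        grad += x[rows].sum(axis=0)
    return loglik, grad, hess


def _tie_groups(time_desc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    change = np.nonzero(np.diff(time_desc))[0] + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [time_desc.size]])
    return starts, stops


def cox_fit_matrix(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    names: tuple[str, ...] | None = None,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFitResult:
    """Newton-Raphson Cox fit with Efron ties on an arbitrary design matrix."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if x.ndim != 2:
        raise ValueError("x must be 2-d")
    n, p = x.shape
    if event.sum() < 1:
        raise ValueError("at least one event required")
    if np.isnan(x).any():
        raise ValueError("design matrix contains missing values")

    order = np.argsort(-time, kind="mergesort")
    xs, ev = x[order], event[order]
    starts, stops = _tie_groups(time[order])
    d_per_group = np.array([ev[a:b].sum() for a, b in zip(starts, stops)])
    center = xs.mean(axis=0)
    xs = xs - center

    beta = np.zeros(p)
    args = (xs, starts, stops, ev, d_per_group)
    ll, grad, hess = _efron_loglik_grad_hess(xs, beta, starts, stops, ev, d_per_group)
    loglik_null = ll
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        ll_new, grad_new, hess_new = _efron_loglik_grad_hess(
            xs, beta + step, starts, stops, ev, d_per_group
        )
        halvings = 0
        while ll_new < ll and halvings < 10:
            step *= 0.5
            ll_new, grad_new, hess_new = _efron_loglik_grad_hess(
                xs, beta + step, starts, stops, ev, d_per_group
            )
            halvings += 1
        beta = beta + step
        done = (
            abs(ll_new - ll) <= tol * (abs(ll) + tol)
            and np.abs(step).max() < 1e-7
        ) or np.abs(step).max() < 1e-12
        ll, grad, hess = ll_new, grad_new, hess_new
        if done:
            converged = True
            break
    loglik = ll
    if np.abs(beta).max() > 50:
        converged = False  # monotone likelihood / infinite estimate

    try:
        vcov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(-hess)
        converged = False
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    return CoxFitResult(
        beta=beta,
        se=se,
        vcov=vcov,
        loglik_null=loglik_null,
        loglik=loglik,
        linear_predictor=x @ beta,
        n=n,
        n_events=int(event.sum()),
        converged=converged,
        names=tuple(names) if names else tuple(f"x{i}" for i in range(p)),
        time=time,
        event=event,
    )


def fit_cox(data: pd.DataFrame, covariates: tuple[str, ...] = COVARIATES) -> CoxFitResult:
    """Fit the prognostic Cox model on all eight covariates (age linear)."""
    x = data[list(covariates)].to_numpy(dtype=float)
    return cox_fit_matrix(
        x, data["time"].to_numpy(), data["event"].to_numpy(), names=covariates
    )


def nagelkerke_r2(fit: CoxFitResult, n: int | None = None) -> float:
    """Likelihood-ratio pseudo R^2 rescaled to a [0, 1] maximum."""
    n = n or fit.n
    if fit.loglik_null == 0.0:
        raise ValueError("null log-likelihood is zero; R^2 undefined")
    r2_cs = 1.0 - math.exp(-(2.0 / n) * (fit.loglik - fit.loglik_null))
    max_r2 = 1.0 - math.exp((2.0 / n) * fit.loglik_null)
    return r2_cs / max_r2


def royston_d(linear_predictor, time, event) -> float:
    """Prognostic separation: Cox slope on the Blom-scored prognostic index.

    Ranks of the linear predictor (ties averaged) are mapped to normal order
    scores z = Phi^-1((r - 3/8) / (n + 1/4)), scaled by kappa = sqrt(8/pi),
    and a univariate Cox model is fitted on that score.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = lp.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if event.sum() < 1:
        raise ValueError("at least one event required")
    if np.ptp(lp) == 0:
        return 0.0
    r = stats.rankdata(lp, method="average")
    z = stats.norm.ppf((r - 3.0 / 8.0) / (n + 0.25)) / KAPPA
    fit = cox_fit_matrix(z[:, None], time, event, names=("score",))
    return float(fit.beta[0])


def breslow_cumhaz(fit: CoxFitResult, t: float) -> float:
    """Breslow baseline cumulative hazard at t for the mean-centred predictor."""
    if fit.time is None or fit.event is None:
        raise ValueError("fit does not carry its data")
    lp = fit.linear_predictor - fit.linear_predictor.mean()
    w = np.exp(lp)
    order = np.argsort(fit.time, kind="mergesort")
    ts, evs, ws = fit.time[order], fit.event[order], w[order]
    # risk-set sums by reverse cumulative sum
    rev = np.cumsum(ws[::-1])[::-1]
    h0 = 0.0
    i = 0
    n = ts.size
    while i < n and ts[i] <= t:
        j = i
        d = 0
        while j < n and ts[j] == ts[i]:
            d += evs[j]
            j += 1
        if d:
            h0 += d / rev[i]
        i = j
    return float(h0)


def predicted_survival(fit: CoxFitResult, t: float) -> float:
    """Average over cases of exp(-H0(t) * exp(PI_i - mean PI))."""
    if fit.time is None:
        raise ValueError("fit does not carry its data")
    if t == 0:
        return 1.0
    if t > fit.time.max():
        raise ValueError(f"t = {t} beyond the last observed time {fit.time.max():.3f}")
    h0 = breslow_cumhaz(fit, t)
    lp = fit.linear_predictor - fit.linear_predictor.mean()
    return float(np.mean(np.exp(-h0 * np.exp(lp))))


def nelson_aalen_at(time, event) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at each case's own time
    (optional imputation-model predictor in place of log time)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="mergesort")
    ts, evs = time[order], event[order]
    n = ts.size
    at_risk = n - np.arange(n)
    # group ties
    haz = np.zeros(n)
    i = 0
    cum = 0.0
    while i < n:
        j = i
        d = 0
        while j < n and ts[j] == ts[i]:
            d += evs[j]
            j += 1
        cum += d / at_risk[i]
        haz[i:j] = cum
        i = j
    out = np.empty(n)
    out[order] = haz
    return out
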