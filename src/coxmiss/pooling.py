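"""Rubin's-rules pooling and estimator evaluation (bias, coverage, efficiency).

Pooled point estimate Q-bar, within-imputation variance W-bar, between-
imputation variance B, total variance T = W + (1 + 1/m) B, and the
(m - 1)(1 + W / ((1 + 1/m) B))^2 degrees of freedom for the t reference
distribution.  Performance measures are pooled on scales chosen to
approximate normality: raw for coefficients and prognostic separation,
complementary log-log for survival probabilities, medians for R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PooledEstimate",
    "TrueValues",
    "rubin_pool",
    "pool_performance",
    "evaluate",
    "required_replications",
]


@dataclass(frozen=True)
class PooledEstimate:
    q_bar: float
    w_bar: float
    b: float  # nan for m = 1
    t_var: float
    df: float  # inf when b = 0 or m = 1
    m: int
    se: float = field(init=False)
    ci: tuple[float, float] = field(init=False)
    p: float = field(init=False)

    def __post_init__(self) -> None:
        se = math.sqrt(self.t_var)
        if math.isinf(self.df):
            q = stats.norm.ppf(0.975)
            p = 2.0 * stats.norm.sf(abs(self.q_bar) / se) if se > 0 else float(self.q_bar == 0)
        else:
            q = stats.t.ppf(0.975, self.df)
            p = 2.0 * stats.t.sf(abs(self.q_bar) / se, self.df) if se > 0 else 0.0
        object.__setattr__(self, "se", se)
        object.__setattr__(self, "ci", (self.q_bar - q * se, self.q_bar + q * se))
        object.__setattr__(self, "p", float(p))


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Combine m complete-data estimates and their variances."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1 or est.size < 1:
        raise ValueError("estimates and variances must be 1-d of equal length >= 1")
    if (var <= 0).any():
        raise ValueError("variances must be positive")
    m = est.size
    q_bar = float(est.mean())
    w_bar = float(var.mean())
    if m == 1:
        return PooledEstimate(q_bar=q_bar, w_bar=w_bar, b=float("nan"),
                              t_var=w_bar, df=float("inf"), m=1)
    b = float(est.var(ddof=1))
    t_var = w_bar + (1.0 + 1.0 / m) * b
    ratio = w_bar / ((1.0 + 1.0 / m) * b) if b > 0 else float("inf")
    if not math.isfinite(ratio) or ratio > 1e8:
        df = float("inf")
    else:
        df = (m - 1) * (1.0 + ratio) ** 2
    return PooledEstimate(q_bar=q_bar, w_bar=w_bar, b=b, t_var=t_var, df=df, m=m)


def pool_performance(values, kind: str) -> float:
    """Pool per-imputation performance values.

    kind='r2': median; kind='d': mean on the raw scale; kind='survival':
    mean on the complementary log-log scale, back-transformed.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    if kind == "r2":
        return float(np.median(v))
    if kind == "d":
        return float(v.mean())
    if kind == "survival":
        v = np.clip(v, 1e-12, 1.0 - 1e-12)
        cloglog = np.log(-np.log(v))
        return float(np.exp(-np.exp(cloglog.mean())))
    raise ValueError(f"unknown kind {kind!r}")


def required_replications(beta: float, se: float, accuracy: float) -> int:
    """Replications needed to estimate beta to the given relative accuracy."""
    if beta == 0:
        raise ValueError("accuracy-based replication count undefined for beta = 0")
    if se <= 0:
        raise ValueError("se must be positive")
    if not 0.0 < accuracy < 1.0:
        raise ValueError("accuracy must be in (0, 1)")
    return int(math.ceil((1.96 * se / (accuracy * abs(beta))) ** 2))


@dataclass
class TrueValues:
    """Complete-data reference values from the truth run."""

    covariates: tuple[str, ...]
    beta_true: np.ndarray
    se_true: np.ndarray  # empirical SD of estimates over the truth replications
    r2_true: float
    d_true: float
    surv2_true: float
    surv5_true: float
    n_replications: int


def evaluate(
    coef_rows: pd.DataFrame,
    perf_rows: pd.DataFrame,
    truth: TrueValues,
    failures: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Summarise per-replication results against the truth.

    coef_rows: one row per (replication, method, p0, covariate) with columns
    est, se, ci_lo, ci_hi, p.  perf_rows: one row per (replication, method,
    p0) with r2, d, surv2, surv5.  Returns tidy coefficient and performance
    summary tables plus a failure tally; failed replications are excluded
    from the means but always reported.
    """
    truth_map = dict(zip(truth.covariates, truth.beta_true))
    se_map = dict(zip(truth.covariates, truth.se_true))

    rows = []
    for (method, p0, cov), g in coef_rows.groupby(["method", "p0", "covariate"], sort=True):
        if len(g) < 2:
            raise ValueError(f"need >= 2 successful replications for {(method, p0, cov)}")
        bt = truth_map[cov]
        st = se_map[cov]
        est = g["est"].to_numpy()
        bias = float(est.mean() - bt)
        covered = ((g["ci_lo"] <= bt) & (bt <= g["ci_hi"])).mean()
        rows.append(
            {
                "method": method,
                "p0": p0,
                "covariate": cov,
                "n_reps": len(g),
                "mean_est": float(est.mean()),
                "bias": bias,
                "pct_bias": 100.0 * bias / bt if bt != 0 else float("nan"),
                "empirical_se": float(est.std(ddof=1)),
                "mean_model_se": float(g["se"].mean()),
                "coverage": float(covered),
                "rejection_rate": float((g["p"] < 0.05).mean()),
                "problematic": bool(abs(bias) > 0.5 * st),
            }
        )
    coef_summary = pd.DataFrame(rows)

    perf = []
    for (method, p0), g in perf_rows.groupby(["method", "p0"], sort=True):
        r2 = g["r2"].to_numpy()
        perf.append(
            {
                "method": method,
                "p0": p0,
                "n_reps": len(g),
                "r2_median": float(np.median(r2)),
                "r2_iqr_lo": float(np.percentile(r2, 25)),
                "r2_iqr_hi": float(np.percentile(r2, 75)),
                "d_mean": float(g["d"].mean()),
                "surv2_mean": float(g["surv2"].mean()),
                "surv5_mean": float(g["surv5"].mean()),
            }
        )
    perf_summary = pd.DataFrame(perf)

    if failures is None or failures.empty:
        fail_summary = pd.DataFrame(columns=["method", "p0", "n_failures"])
    else:
        fail_summary = (
            failures.groupby(["method", "p0"]).size().rename("n_failures").reset_index()
        )
    return {
        "coefficients": coef_summary,
        "performance": perf_summary,
        "failures": fail_summary,
    }
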