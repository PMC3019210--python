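"""The five missing-data methods: CC, SI, MICE, MICE-PMM and additive-PMM.

All engines are implemented from first principles.  The chained-equations
engines cycle through the incomplete columns (age by linear regression,
stage / post_rt by logistic regression), refit each conditional model on the
currently-completed data with a *proper* parameter draw, and impute either by
drawing from the model (MICE) or by predictive mean matching on the drawn
predictions (SI / MICE-PMM).  The additive engine replaces the linear terms
for continuous predictors by a restricted-cubic-spline expansion and
propagates model uncertainty by refitting on a bootstrap resample each cycle.

Imputation-model predictors: all other covariates, the event status and
log survival time (optionally the Nelson-Aalen cumulative hazard instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .amputation import AMPUTABLE, IncompleteDataset
from .population import COVARIATES
from .survival import nelson_aalen_at

__all__ = [
    "ImputationConfig",
    "complete_case_filter",
    "pmm_impute_column",
    "chained_impute",
    "areg_impute",
    "impute",
    "rcs_basis",
    "ENGINES",
]

ENGINES = ("CC", "SI", "MICE", "MICE-PMM", "AREG-PMM")
BINARY_AMPUTABLE = ("stage", "post_rt")


@dataclass(frozen=True)
class ImputationConfig:
    m: int = 10
    n_cycles: int = 5
    donor_pool_k: int = 3
    engine: str = "MICE-PMM"
    use_nelson_aalen: bool = False
    n_spline_knots: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {ENGINES}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.engine == "SI" and self.m != 1:
            raise ValueError("SI produces exactly one completion (m = 1)")
        if self.donor_pool_k < 1:
            raise ValueError("donor_pool_k must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


class ImputationError(RuntimeError):
    pass


def complete_case_filter(inc: IncompleteDataset) -> pd.DataFrame:
    """Drop every case with any masked covariate."""
    keep = ~inc.incomplete_rows
    if not keep.any():
        raise ImputationError("no complete cases remain; CC analysis infeasible")
    out = inc.data.loc[keep].reset_index(drop=True)
    for col in BINARY_AMPUTABLE:
        out[col] = out[col].astype(np.int64)
    return out


def pmm_impute_column(
    pred_missing: np.ndarray,
    pred_observed: np.ndarray,
    observed_values: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Predictive mean matching: donate the observed value of one of the k
    observed cases whose predictions are nearest each missing prediction."""
    pred_missing = np.asarray(pred_missing, dtype=float)
    pred_observed = np.asarray(pred_observed, dtype=float)
    observed_values = np.asarray(observed_values)
    n_obs = pred_observed.size
    if n_obs == 0:
        raise ImputationError("no observed cases to donate from")
    if n_obs < k:
        warnings.warn(f"donor pool shrunk from {k} to {n_obs} observed cases")
        k = n_obs
    # |missing x observed| distance matrix; fine at study sizes
    dist = np.abs(pred_missing[:, None] - pred_observed[None, :])
    if k == 1:
        donors = np.argmin(dist, axis=1)
    else:
        pools = np.argpartition(dist, k - 1, axis=1)[:, :k]
        choice = rng.integers(0, k, size=pred_missing.size)
        donors = pools[np.arange(pred_missing.size), choice]
    return observed_values[donors]


# ---------------------------------------------------------------------------
# conditional models with proper parameter draws
# ---------------------------------------------------------------------------


def _draw_linear(y, x, rng):
    """OLS fit + Bayesian draw of (beta, sigma); returns (beta_star, sigma_star)."""
    n, p = x.shape
    xtx = x.T @ x
    xty = x.T @ y
    ridge = 1e-8 * np.trace(xtx) / p
    try:
        beta_hat = np.linalg.solve(xtx, xty)
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        xtx = xtx + ridge * np.eye(p)
        beta_hat = np.linalg.solve(xtx, xty)
        xtx_inv = np.linalg.inv(xtx)
    resid = y - x @ beta_hat
    df = max(n - p, 1)
    sigma2_star = float(resid @ resid) / stats.chi2.rvs(df, random_state=rng)
    cov = xtx_inv * sigma2_star
    cov = (cov + cov.T) / 2
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-8 * np.trace(cov) / p * np.eye(p))
    beta_star = beta_hat + chol @ rng.standard_normal(p)
    return beta_star, np.sqrt(sigma2_star)


def _fit_logistic(y, x, ridge: float = 1e-6, max_iter: int = 30):
    """IRLS logistic fit; returns (beta_hat, covariance).  Separation is
    stabilised by increasing the ridge penalty."""
    n, p = x.shape
    beta = np.zeros(p)
    lam = ridge
    for attempt in range(3):
        ok = True
        beta = np.zeros(p)
        for _ in range(max_iter):
            eta = np.clip(x @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            grad = x.T @ (y - mu) - lam * beta
            hess = (x * w[:, None]).T @ x + lam * np.eye(p)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                ok = False
                break
            beta = beta + step
            if np.abs(step).max() < 1e-8:
                break
        if ok and np.abs(beta).max() < 15:
            break
        warnings.warn("possible separation in logistic conditional; ridge-stabilised refit")
        lam = max(lam * 1000, 0.1)
    eta = np.clip(x @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    hess = (x * w[:, None]).T @ x + lam * np.eye(p)
    cov = np.linalg.inv(hess)
    return beta, (cov + cov.T) / 2


def _draw_logistic(y, x, rng):
    """Asymptotic-normal proper draw around the (ridge-stabilised) MLE."""
    beta_hat, cov = _fit_logistic(y, x)
    p = beta_hat.size
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-8 * np.trace(cov) / p * np.eye(p))
    return beta_hat + chol @ rng.standard_normal(p)


# ---------------------------------------------------------------------------
# restricted cubic splines (additive engine)
# ---------------------------------------------------------------------------


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Harrell's restricted cubic spline basis: linear term + k-2 nonlinear
    terms, linear beyond the boundary knots."""
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = knots.size
    if k < 3:
        return x[:, None]
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    norm = (tk - t1) ** 2
    cols = [x]
    pos3 = lambda u: np.clip(u, 0.0, None) ** 3
    for j in range(k - 2):
        tj = knots[j]
        term = (
            pos3(x - tj)
            - pos3(x - tk1) * (tk - tj) / (tk - tk1)
            + pos3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def _spline_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    qs = {3: (0.10, 0.50, 0.90), 4: (0.05, 0.35, 0.65, 0.95), 5: (0.05, 0.275, 0.50, 0.725, 0.95)}
    q = qs.get(n_knots, tuple(np.linspace(0.05, 0.95, n_knots)))
    knots = np.quantile(x, q)
    knots = np.unique(knots)
    if knots.size < n_knots:
        warnings.warn("tied quantiles collapsed spline knots; reducing knot count")
    return knots


# ---------------------------------------------------------------------------
# chained-equations engine
# ---------------------------------------------------------------------------

_CONTINUOUS_PREDICTORS = ("age", "log_time")


def _outcome_predictors(data: pd.DataFrame, use_nelson_aalen: bool) -> pd.DataFrame:
    if use_nelson_aalen:
        haz = nelson_aalen_at(data["time"].to_numpy(), data["event"].to_numpy())
        out = pd.DataFrame({"cumhaz": haz, "event": data["event"].to_numpy(dtype=float)})
    else:
        out = pd.DataFrame(
            {
                "log_time": np.log(data["time"].to_numpy()),
                "event": data["event"].to_numpy(dtype=float),
            }
        )
    return out


def _design(
    completed: pd.DataFrame,
    outcome: pd.DataFrame,
    target: str,
    spline: bool,
    n_knots: int,
) -> np.ndarray:
    """Design matrix for the conditional model of ``target``: intercept, the
    other 7 covariates, event status and (log time | cumulative hazard)."""
    cols = [c for c in COVARIATES if c != target]
    parts = [np.ones((len(completed), 1))]
    for c in cols:
        v = completed[c].to_numpy(dtype=float)
        if spline and c == "age":
            parts.append(rcs_basis(v, _spline_knots(v, n_knots)))
        else:
            parts.append(v[:, None])
    for c in outcome.columns:
        v = outcome[c].to_numpy(dtype=float)
        if spline and c in ("log_time", "cumhaz"):
            parts.append(rcs_basis(v, _spline_knots(v, n_knots)))
        else:
            parts.append(v[:, None])
    return np.hstack(parts)


def _initial_fill(
    inc: IncompleteDataset, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Random draws from each column's observed values; returns the completed
    frame and the per-column missing-row indices."""
    completed = inc.data.copy()
    missing_rows: dict[str, np.ndarray] = {}
    for col in AMPUTABLE:
        mis = inc.mask[col].to_numpy()
        if not mis.any():
            continue
        obs_vals = inc.data.loc[~mis, col].to_numpy()
        if obs_vals.size == 0:
            raise ImputationError(f"column {col} has no observed values")
        completed.loc[mis, col] = rng.choice(obs_vals, size=int(mis.sum()))
        missing_rows[col] = np.nonzero(mis)[0]
    return completed, missing_rows


def _visit_order(inc: IncompleteDataset) -> list[str]:
    frac = inc.mask.mean(axis=0)
    return [c for c in frac.sort_values(kind="mergesort").index if frac[c] > 0]


def _finalise(completed: pd.DataFrame, engine: str, index: int, source_hash: int) -> pd.DataFrame:
    for col in BINARY_AMPUTABLE:
        completed[col] = completed[col].round().astype(np.int64)
    completed.attrs["engine"] = engine
    completed.attrs["imputation"] = index
    completed.attrs["source_hash"] = source_hash
    return completed


def chained_impute(
    inc: IncompleteDataset,
    config: ImputationConfig,
    rng: np.random.Generator | None = None,
) -> list[pd.DataFrame]:
    """Regression-switching MI; parametric draws (MICE) or PMM (SI/MICE-PMM)."""
    if config.engine not in ("SI", "MICE", "MICE-PMM"):
        raise ValueError(f"chained_impute does not run engine {config.engine}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    use_pmm = config.engine in ("SI", "MICE-PMM")
    source_hash = int(pd.util.hash_pandas_object(inc.data.fillna(-1)).sum())
    outcome = _outcome_predictors(inc.data, config.use_nelson_aalen)
    order = _visit_order(inc)
    if not order:
        return [
            _finalise(inc.data.copy(), config.engine, j, source_hash)
            for j in range(config.m)
        ]

    out = []
    for j in range(config.m):
        completed, missing_rows = _initial_fill(inc, rng)
        for _ in range(config.n_cycles):
            for col in order:
                mis_idx = missing_rows[col]
                obs = np.ones(len(completed), dtype=bool)
                obs[mis_idx] = False
                x = _design(completed, outcome, col, spline=False, n_knots=0)
                y_obs = inc.data.loc[obs, col].to_numpy(dtype=float)
                if col == "age":
                    beta_star, sigma_star = _draw_linear(y_obs, x[obs], rng)
                    pred = x @ beta_star
                    if use_pmm:
                        imputed = pmm_impute_column(
                            pred[mis_idx], pred[obs], y_obs, config.donor_pool_k, rng
                        )
                    else:
                        imputed = pred[mis_idx] + sigma_star * rng.standard_normal(
                            mis_idx.size
                        )
                else:
                    beta_star = _draw_logistic(y_obs, x[obs], rng)
                    pred = x @ beta_star  # linear-predictor scale
                    if use_pmm:
                        imputed = pmm_impute_column(
                            pred[mis_idx], pred[obs], y_obs, config.donor_pool_k, rng
                        )
                    else:
                        prob = 1.0 / (1.0 + np.exp(-np.clip(pred[mis_idx], -30, 30)))
                        imputed = (rng.uniform(size=mis_idx.size) < prob).astype(float)
                completed.iloc[mis_idx, completed.columns.get_loc(col)] = imputed
        out.append(_finalise(completed, config.engine, j, source_hash))
    return out


def areg_impute(
    inc: IncompleteDataset,
    config: ImputationConfig,
    rng: np.random.Generator | None = None,
) -> list[pd.DataFrame]:
    """Additive-model MI: spline-expanded conditionals, bootstrap refitting
    for parameter uncertainty, imputation by PMM on the predicted scale."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    source_hash = int(pd.util.hash_pandas_object(inc.data.fillna(-1)).sum())
    outcome = _outcome_predictors(inc.data, config.use_nelson_aalen)
    order = _visit_order(inc)
    if not order:
        return [
            _finalise(inc.data.copy(), "AREG-PMM", j, source_hash)
            for j in range(config.m)
        ]

    out = []
    for j in range(config.m):
        completed, missing_rows = _initial_fill(inc, rng)
        for _ in range(config.n_cycles):
            for col in order:
                mis_idx = missing_rows[col]
                obs = np.ones(len(completed), dtype=bool)
                obs[mis_idx] = False
                x = _design(
                    completed, outcome, col, spline=True, n_knots=config.n_spline_knots
                )
                y_obs = inc.data.loc[obs, col].to_numpy(dtype=float)
                obs_idx = np.nonzero(obs)[0]
                boot = rng.integers(0, obs_idx.size, size=obs_idx.size)
                xb, yb = x[obs_idx[boot]], y_obs[boot]
                if col == "age":
                    xtx = xb.T @ xb + 1e-8 * np.eye(xb.shape[1])
                    beta_b = np.linalg.solve(xtx, xb.T @ yb)
                else:
                    beta_b, _ = _fit_logistic(yb, xb)
                pred = x @ beta_b
                imputed = pmm_impute_column(
                    pred[mis_idx], pred[obs], y_obs, config.donor_pool_k, rng
                )
                completed.iloc[mis_idx, completed.columns.get_loc(col)] = imputed
        out.append(_finalise(completed, "AREG-PMM", j, source_hash))
    return out


def impute(
    inc: IncompleteDataset,
    config: ImputationConfig,
    rng: np.random.Generator | None = None,
) -> list[pd.DataFrame]:
    """Dispatch on the configured engine; CC returns a single filtered frame."""
    if config.engine == "CC":
        return [complete_case_filter(inc)]
    if config.engine == "AREG-PMM":
        return areg_impute(inc, config, rng)
    return chained_impute(inc, config, rng)
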