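"""Orchestration of the factorial resampling study.

For every replication a bootstrap sample of n cases is drawn from the
synthetic population; missingness is imposed at each rate in the p0 grid;
each missing-data method completes the sample; the 8-covariate Cox model is
fitted to every completed dataset; MI results are pooled by Rubin's rules.
All methods see the same samples and the same amputations.  Every
replication's random stream is derived deterministically from
(master_seed, replication index), so execution order is irrelevant.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pooling
from .amputation import DEFAULT_PATTERN_TABLE, AmputationConfig, PatternTable, impose_mar
from .impute import ENGINES, ImputationConfig, ImputationError, impute
from .pooling import TrueValues, evaluate, rubin_pool, pool_performance
from .population import (
    COVARIATES,
    PopulationConfig,
    draw_bootstrap_sample,
    generate_population,
)
from .survival import fit_cox, nagelkerke_r2, predicted_survival, royston_d

__all__ = ["StudyConfig", "run_truth", "run_study", "write_report"]

log = logging.getLogger("coxmiss")

DEFAULT_P0_GRID = (0.05, 0.10, 0.25, 0.50, 0.75)


@dataclass(frozen=True)
class StudyConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    n_sample: int = 1000
    n_replications: int = 500
    p0_grid: tuple[float, ...] = DEFAULT_P0_GRID
    methods: tuple[str, ...] = ENGINES
    m_imputations: int = 10
    n_cycles: int = 5
    donor_pool_k: int = 3
    truth_replications: int = 2000
    master_seed: int = 0
    pattern_table: PatternTable = DEFAULT_PATTERN_TABLE

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ENGINES)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if self.n_replications < 1 or self.n_sample < 1:
            raise ValueError("n_replications and n_sample must be >= 1")


def _rep_rng(master_seed: int, stream: str, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(stream.encode()), index])
    )


def _fit_measures(df: pd.DataFrame, horizons=(2.0, 5.0)):
    fit = fit_cox(df)
    if not fit.converged:
        raise ImputationError("Cox fit failed to converge")
    r2 = nagelkerke_r2(fit)
    d = royston_d(fit.linear_predictor, df["time"].to_numpy(), df["event"].to_numpy())
    tmax = df["time"].max()
    surv = [predicted_survival(fit, min(t, tmax)) for t in horizons]
    return fit, r2, d, surv


def run_truth(config: StudyConfig) -> TrueValues:
    """Complete-data replications defining the reference 'true' values."""
    if config.truth_replications < 2:
        raise ValueError("truth run needs >= 2 replications for an empirical SE")
    pop = generate_population(
        dataclasses.replace(config.population, seed=config.master_seed)
    )
    betas, r2s, ds, s2s, s5s = [], [], [], [], []
    for r in range(config.truth_replications):
        rng = _rep_rng(config.master_seed, "truth", r)
        samp = draw_bootstrap_sample(pop, config.n_sample, rng)
        try:
            fit, r2, d, (s2, s5) = _fit_measures(samp)
        except Exception as exc:  # noqa: BLE001 - recorded, never raised
            log.warning("truth replication %d failed: %s", r, exc)
            continue
        betas.append(fit.beta)
        r2s.append(r2)
        ds.append(d)
        s2s.append(s2)
        s5s.append(s5)
    betas = np.array(betas)
    if betas.shape[0] < 2:
        raise RuntimeError("fewer than 2 successful truth replications")
    return TrueValues(
        covariates=COVARIATES,
        beta_true=betas.mean(axis=0),
        se_true=betas.std(axis=0, ddof=1),
        r2_true=float(np.median(r2s)),
        d_true=float(np.mean(ds)),
        surv2_true=float(np.mean(s2s)),
        surv5_true=float(np.mean(s5s)),
        n_replications=betas.shape[0],
    )


def _method_config(method: str, config: StudyConfig) -> ImputationConfig:
    m = 1 if method in ("CC", "SI") else config.m_imputations
    return ImputationConfig(
        m=m,
        n_cycles=config.n_cycles,
        donor_pool_k=config.donor_pool_k,
        engine=method,
    )


def _analyse_method(
    method: str,
    inc,
    config: StudyConfig,
    rng: np.random.Generator,
):
    """Complete/impute, fit Cox per completion, pool.  Returns (coef dict
    rows, perf row)."""
    completions = impute(inc, _method_config(method, config), rng)
    fits, r2s, ds, s2s, s5s = [], [], [], [], []
    for comp in completions:
        fit, r2, d, (s2, s5) = _fit_measures(comp)
        fits.append(fit)
        r2s.append(r2)
        ds.append(d)
        s2s.append(s2)
        s5s.append(s5)
    m = len(fits)
    coef_rows = []
    for j, cov in enumerate(COVARIATES):
        est = np.array([f.beta[j] for f in fits])
        var = np.array([f.se[j] ** 2 for f in fits])
        pooled = rubin_pool(est, var)
        coef_rows.append(
            {
                "covariate": cov,
                "est": pooled.q_bar,
                "se": pooled.se,
                "ci_lo": pooled.ci[0],
                "ci_hi": pooled.ci[1],
                "p": pooled.p,
            }
        )
    perf = {
        "r2": pool_performance(r2s, "r2"),
        "d": pool_performance(ds, "d"),
        "surv2": pool_performance(s2s, "survival"),
        "surv5": pool_performance(s5s, "survival"),
        "m": m,
    }
    return coef_rows, perf


def run_study(config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Run the full factorial study; returns raw per-replication tables."""
    pop = generate_population(
        dataclasses.replace(config.population, seed=config.master_seed)
    )
    coef_records, perf_records, failures = [], [], []
    for r in range(config.n_replications):
        rng = _rep_rng(config.master_seed, "study", r)
        samp = draw_bootstrap_sample(pop, config.n_sample, rng)
        for p0 in config.p0_grid:
            if p0 > 0:
                amp_rng = _rep_rng(config.master_seed, f"ampute-{p0}", r)
                inc = impose_mar(samp, config.pattern_table, AmputationConfig(p0=p0), amp_rng)
            else:
                from .amputation import AMPUTABLE, IncompleteDataset

                inc = IncompleteDataset(
                    data=samp.copy(),
                    mask=pd.DataFrame(
                        np.zeros((len(samp), 3), dtype=bool), columns=list(AMPUTABLE)
                    ),
                )
            for method in config.methods:
                meth_rng = _rep_rng(config.master_seed, f"{method}-{p0}", r)
                try:
                    coef_rows, perf = _analyse_method(method, inc, config, meth_rng)
                except Exception as exc:  # noqa: BLE001
                    log.warning(
                        "replication %d method %s p0 %.2f failed: %s", r, method, p0, exc
                    )
                    failures.append(
                        {"replication": r, "method": method, "p0": p0, "reason": str(exc)}
                    )
                    continue
                for row in coef_rows:
                    coef_records.append(
                        {"replication": r, "method": method, "p0": p0, **row}
                    )
                perf_records.append(
                    {"replication": r, "method": method, "p0": p0, **perf}
                )
    return {
        "coefficients": pd.DataFrame(coef_records),
        "performance": pd.DataFrame(perf_records),
        "failures": pd.DataFrame(failures, columns=["replication", "method", "p0", "reason"]),
    }


def write_report(
    raw: dict[str, pd.DataFrame],
    truth: TrueValues,
    out_dir: str | Path,
) -> dict[str, pd.DataFrame]:
    """Evaluate raw tables against the truth and write tidy TSV reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = evaluate(raw["coefficients"], raw["performance"], truth, raw["failures"])
    for name, df in raw.items():
        df.to_csv(out / f"raw_{name}.tsv", sep="\t", index=False)
    for name, df in summary.items():
        df.to_csv(out / f"summary_{name}.tsv", sep="\t", index=False)
    truth_df = pd.DataFrame(
        {
            "covariate": truth.covariates,
            "beta_true": truth.beta_true,
            "se_true": truth.se_true,
        }
    )
    truth_df.to_csv(out / "truth_coefficients.tsv", sep="\t", index=False)
    return summary
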