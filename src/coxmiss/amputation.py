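"""Multivariate MAR amputation of stage, post_rt and age.

A complete dataset is turned into an incomplete one in two steps: a fixed
number round(p0 * n) of cases is selected without replacement with
probability weights given by a logistic MAR score (shorter survival, rectal
site, clear CT indication and the case's own stage / post-RT / age values all
raise the selection probability), then each selected case independently
receives one of seven missingness patterns over (stage, post_rt, age) drawn
with the packaged pattern frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import COVARIATES

__all__ = [
    "AMPUTABLE",
    "PatternTable",
    "DEFAULT_PATTERN_TABLE",
    "AmputationConfig",
    "IncompleteDataset",
    "impose_mar",
    "missingness_summary",
    "write_incomplete",
    "read_incomplete",
]

AMPUTABLE = ("stage", "post_rt", "age")

# MAR score features and their default signed weights: missingness is more
# likely with shorter survival, rectal/both site, clear CT indication and
# higher observed stage, planned post-operative RT and older age.  The source
# study states directions only; the outcome weight is calibrated so that
# complete-case bias grows visibly with the missingness rate while the
# imputation methods stay close to the truth (the study's headline contrast).
MAR_FEATURES = ("neg_log_time", "site", "ct_indic_clear", "stage", "post_rt", "age")
DEFAULT_MAR_WEIGHTS: dict[str, float] = {f: 1.0 for f in MAR_FEATURES}
DEFAULT_MAR_WEIGHTS["neg_log_time"] = 3.0


@dataclass(frozen=True)
class PatternTable:
    """Missingness patterns over (stage, post_rt, age); 1 = observed."""

    patterns: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        pat = np.asarray(self.patterns, dtype=int)
        freq = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "patterns", pat)
        object.__setattr__(self, "frequencies", freq)
        if pat.ndim != 2 or pat.shape[1] != len(AMPUTABLE):
            raise ValueError(f"patterns must be (k, {len(AMPUTABLE)})")
        if freq.shape != (pat.shape[0],):
            raise ValueError("one frequency per pattern required")
        if not np.isin(pat, (0, 1)).all():
            raise ValueError("patterns must be 0/1")
        if abs(freq.sum() - 1.0) > 1e-12:
            raise ValueError("pattern frequencies must sum to 1")
        if (freq < 0).any():
            raise ValueError("pattern frequencies must be non-negative")
        if (pat.sum(axis=1) == pat.shape[1]).any():
            raise ValueError("an all-observed pattern is not a missingness pattern")

    @property
    def n_missing_per_pattern(self) -> np.ndarray:
        return (self.patterns == 0).sum(axis=1)

    def expected_missing_items_per_incomplete_case(self) -> float:
        return float(self.frequencies @ self.n_missing_per_pattern)

    def marginal_missing_fraction(self) -> dict[str, float]:
        """Per covariate: probability it is missing given the case is incomplete."""
        frac = self.frequencies @ (self.patterns == 0)
        return dict(zip(AMPUTABLE, frac.astype(float)))


# The seven patterns and frequencies observed in the ovarian-cancer source
# study (columns: stage, post_rt, age; 1 = observed).
DEFAULT_PATTERN_TABLE = PatternTable(
    patterns=np.array(
        [
            [1, 1, 0],
            [1, 0, 1],
            [1, 0, 0],
            [0, 1, 1],
            [0, 1, 0],
            [0, 0, 1],
            [0, 0, 0],
        ]
    ),
    frequencies=np.array([0.08, 0.17, 0.04, 0.25, 0.04, 0.34, 0.08]),
)


@dataclass(frozen=True)
class AmputationConfig:
    p0: float = 0.25
    mar_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MAR_WEIGHTS))
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0, 1)")
        unknown = set(self.mar_weights) - set(MAR_FEATURES)
        if unknown:
            raise ValueError(f"unknown MAR features {sorted(unknown)}")


@dataclass
class IncompleteDataset:
    """A dataset with NaNs in the amputable columns plus the explicit mask."""

    data: pd.DataFrame
    mask: pd.DataFrame  # boolean, columns AMPUTABLE, True = missing

    def __post_init__(self) -> None:
        if list(self.mask.columns) != list(AMPUTABLE):
            raise ValueError(f"mask columns must be {AMPUTABLE}")
        if len(self.mask) != len(self.data):
            raise ValueError("mask and data lengths differ")

    @property
    def incomplete_rows(self) -> np.ndarray:
        return self.mask.to_numpy().any(axis=1)

    @property
    def n_incomplete(self) -> int:
        return int(self.incomplete_rows.sum())


def _mar_scores(data: pd.DataFrame, weights: dict[str, float]) -> np.ndarray:
    feats = {
        "neg_log_time": -np.log(data["time"].to_numpy()),
        "site": data["site"].to_numpy(dtype=float),
        # ct_indic is coded 1 = uncertain, so a *clear* indication is 1 - x
        "ct_indic_clear": 1.0 - data["ct_indic"].to_numpy(dtype=float),
        "stage": data["stage"].to_numpy(dtype=float),
        "post_rt": data["post_rt"].to_numpy(dtype=float),
        "age": data["age"].to_numpy(dtype=float),
    }
    score = np.zeros(len(data))
    for name, w in weights.items():
        f = feats[name]
        sd = f.std()
        if sd > 0:
            score = score + w * (f - f.mean()) / sd
    return score


def impose_mar(
    data: pd.DataFrame,
    patterns: PatternTable = DEFAULT_PATTERN_TABLE,
    config: AmputationConfig = AmputationConfig(),
    rng: np.random.Generator | None = None,
) -> IncompleteDataset:
    """Ampute exactly round(p0 * n) cases according to the MAR mechanism."""
    if data[list(COVARIATES)].isna().any().any():
        raise ValueError("input dataset must be complete")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(data)
    k = int(round(config.p0 * n))
    if k < 1:
        raise ValueError(f"p0 = {config.p0} selects no cases at n = {n}")

    score = _mar_scores(data, config.mar_weights)
    if score.std() == 0:
        warnings.warn("degenerate MAR score; falling back to uniform selection")
        w = np.full(n, 1.0 / n)
    else:
        w = 1.0 / (1.0 + np.exp(-score))
        w = w / w.sum()
    selected = rng.choice(n, size=k, replace=False, p=w)
    pat_idx = rng.choice(len(patterns.frequencies), size=k, p=patterns.frequencies)

    mask = pd.DataFrame(
        np.zeros((n, len(AMPUTABLE)), dtype=bool), columns=list(AMPUTABLE)
    )
    miss = patterns.patterns[pat_idx] == 0
    mask.iloc[selected] = miss

    out = data.copy()
    for j, col in enumerate(AMPUTABLE):
        vals = out[col].to_numpy(dtype=float).copy()
        vals[mask[col].to_numpy()] = np.nan
        out[col] = vals
    return IncompleteDataset(data=out, mask=mask)


def missingness_summary(inc: IncompleteDataset) -> dict:
    """Realised rates, pattern frequencies, availability and MAR diagnostics."""
    data, mask = inc.data, inc.mask.to_numpy()
    n = len(data)
    incomplete = mask.any(axis=1)
    n_inc = int(incomplete.sum())
    n_items = n * len(COVARIATES)
    pct_available = 100.0 * (1.0 - mask.sum() / n_items)

    pattern_freqs: dict[tuple[int, ...], float] = {}
    if n_inc:
        pats, counts = np.unique((~mask[incomplete]).astype(int), axis=0, return_counts=True)
        pattern_freqs = {tuple(p): c / n_inc for p, c in zip(pats, counts)}

    per_cov = {col: 100.0 * mask[:, j].mean() for j, col in enumerate(AMPUTABLE)}
    summary = {
        "n": n,
        "realized_p0": n_inc / n,
        "pct_items_available": pct_available,
        "pattern_frequencies": pattern_freqs,
        "pct_missing_per_covariate": per_cov,
    }
    if n_inc and n_inc < n:
        comp = ~incomplete
        age = data["age"].to_numpy(dtype=float)
        time = data["time"].to_numpy()
        summary["mar_diagnostics"] = {
            "mean_age_complete": float(np.nanmean(age[comp])),
            "mean_age_incomplete": float(np.nanmean(age[incomplete])),
            "median_time_complete": float(np.median(time[comp])),
            "median_time_incomplete": float(np.median(time[incomplete])),
        }
    return summary


def write_incomplete(inc: IncompleteDataset, path) -> None:
    """Delimiter-separated text with blank fields for masked entries."""
    inc.data.to_csv(path, index=False, na_rep="")


def read_incomplete(path) -> IncompleteDataset:
    df = pd.read_csv(path)
    mask = df[list(AMPUTABLE)].isna()
    mask.columns = list(AMPUTABLE)
    return IncompleteDataset(data=df, mask=mask)
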