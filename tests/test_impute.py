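import numpy as np
import pandas as pd
import pytest

from coxmiss.amputation import AMPUTABLE, DEFAULT_PATTERN_TABLE, AmputationConfig, IncompleteDataset, impose_mar
from coxmiss.impute import (
    ImputationConfig,
    ImputationError,
    areg_impute,
    chained_impute,
    complete_case_filter,
    impute,
    pmm_impute_column,
    rcs_basis,
)


def _empty_mask(n):
    return pd.DataFrame(np.zeros((n, 3), dtype=bool), columns=list(AMPUTABLE))


class TestCompleteCase:
    def test_identity_when_complete(self, sample1000):
        inc = IncompleteDataset(data=sample1000.copy(), mask=_empty_mask(len(sample1000)))
        out = complete_case_filter(inc)
        pd.testing.assert_frame_equal(out, sample1000, check_dtype=False)

    def test_enumerated_row_count(self, sample1000):
        inc_data = sample1000.head(5).copy().astype({"stage": float})
        mask = _empty_mask(5)
        mask.iloc[1, 0] = True  # stage missing
        mask.iloc[3, 2] = True  # age missing
        inc_data.loc[1, "stage"] = np.nan
        inc_data.loc[3, "age"] = np.nan
        out = complete_case_filter(IncompleteDataset(data=inc_data, mask=mask))
        assert len(out) == 3

    def test_retained_fraction(self, incomplete50):
        out = complete_case_filter(incomplete50)
        assert len(out) == len(incomplete50.data) - incomplete50.n_incomplete

    def test_zero_complete_rows_error(self, sample1000):
        data = sample1000.head(4).copy().astype({"age": float})
        mask = _empty_mask(4)
        mask["age"] = True
        data["age"] = np.nan
        with pytest.raises(ImputationError, match="infeasib"):
            complete_case_filter(IncompleteDataset(data=data, mask=mask))


class TestPMM:
    def test_single_donor_always_chosen(self, rng):
        out = pmm_impute_column(
            np.array([5.0, -1.0]), np.array([2.0]), np.array([42.0]), k=1, rng=rng
        )
        assert (out == 42.0).all()

    def test_nearest_neighbour_enumeration(self, rng):
        out = pmm_impute_column(
            np.array([1.1]), np.array([1.0, 2.0, 3.0]), np.array([1, 2, 3]), k=1, rng=rng
        )
        assert out[0] == 1

    def test_imputed_values_in_observed_support(self, rng):
        obs_vals = np.array([10.0, 20.0, 30.0, 40.0])
        preds_obs = np.array([0.1, 0.5, 0.9, 1.3])
        out = pmm_impute_column(rng.uniform(0, 1.5, 50), preds_obs, obs_vals, k=3, rng=rng)
        assert np.isin(out, obs_vals).all()

    def test_pool_shrinks_with_warning(self, rng):
        with pytest.warns(UserWarning, match="donor pool"):
            out = pmm_impute_column(
                np.array([0.0]), np.array([1.0, 2.0]), np.array([7.0, 8.0]), k=5, rng=rng
            )
        assert out[0] in (7.0, 8.0)

    def test_no_donors_error(self, rng):
        with pytest.raises(ImputationError):
            pmm_impute_column(np.array([0.0]), np.array([]), np.array([]), k=1, rng=rng)


@pytest.fixture(scope="module")
def incomplete25(sample1000):
    rng = np.random.default_rng(21)
    return impose_mar(sample1000, DEFAULT_PATTERN_TABLE, AmputationConfig(p0=0.25), rng)


ENGINE_CASES = [
    ("SI", 1, chained_impute),
    ("MICE", 3, chained_impute),
    ("MICE-PMM", 3, chained_impute),
    ("AREG-PMM", 3, areg_impute),
]


class TestEngines:
    @pytest.mark.parametrize("engine,m,fn", ENGINE_CASES)
    def test_completions_are_complete_and_preserve_observed(self, incomplete25, engine, m, fn):
        cfg = ImputationConfig(m=m, engine=engine, n_cycles=3)
        out = fn(incomplete25, cfg, np.random.default_rng(5))
        assert len(out) == m
        obs = ~incomplete25.mask.to_numpy()
        src = incomplete25.data[list(AMPUTABLE)].to_numpy(dtype=float)
        for comp in out:
            assert not comp.isna().any().any()
            got = comp[list(AMPUTABLE)].to_numpy(dtype=float)
            # observed entries bit-identical
            assert (got[obs] == src[obs]).all()
            assert set(np.unique(comp["stage"])) <= {0, 1}
            assert set(np.unique(comp["post_rt"])) <= {0, 1}

    @pytest.mark.parametrize("engine,m,fn", ENGINE_CASES)
    def test_no_missingness_returns_identity_copies(self, sample1000, engine, m, fn):
        inc = IncompleteDataset(data=sample1000.copy(), mask=_empty_mask(len(sample1000)))
        out = fn(inc, ImputationConfig(m=m, engine=engine), np.random.default_rng(5))
        assert len(out) == m
        for comp in out:
            pd.testing.assert_frame_equal(
                comp.reset_index(drop=True), sample1000, check_dtype=False
            )

    def test_pmm_closure_for_age(self, incomplete25):
        cfg = ImputationConfig(m=2, engine="MICE-PMM", n_cycles=3)
        out = chained_impute(incomplete25, cfg, np.random.default_rng(1))
        mis = incomplete25.mask["age"].to_numpy()
        observed_ages = set(incomplete25.data.loc[~mis, "age"])
        for comp in out:
            assert set(comp.loc[mis, "age"]) <= observed_ages

    def test_between_imputation_variability(self, incomplete25):
        cfg = ImputationConfig(m=4, engine="MICE-PMM", n_cycles=3)
        out = chained_impute(incomplete25, cfg, np.random.default_rng(2))
        mis = incomplete25.mask["age"].to_numpy()
        stacked = np.array([comp.loc[mis, "age"].to_numpy() for comp in out])
        assert np.ptp(stacked, axis=0).max() > 0

    def test_si_is_single_completion(self):
        with pytest.raises(ValueError, match="one completion"):
            ImputationConfig(m=3, engine="SI")

    def test_mice_binary_draws_are_legal(self, incomplete25):
        out = chained_impute(
            incomplete25, ImputationConfig(m=2, engine="MICE", n_cycles=3),
            np.random.default_rng(3),
        )
        for comp in out:
            assert set(np.unique(comp["stage"])) <= {0, 1}

    def test_areg_on_duplicate_heavy_sample(self, population):
        rng = np.random.default_rng(9)
        idx = rng.integers(0, 40, size=300)  # massive duplication
        samp = population.iloc[idx].reset_index(drop=True)
        inc = impose_mar(samp, DEFAULT_PATTERN_TABLE, AmputationConfig(p0=0.3), rng)
        out = areg_impute(inc, ImputationConfig(m=2, engine="AREG-PMM", n_cycles=2), rng)
        assert len(out) == 2
        for comp in out:
            assert not comp.isna().any().any()

    def test_dispatch(self, incomplete25):
        out = impute(incomplete25, ImputationConfig(m=1, engine="CC"), np.random.default_rng(0))
        assert len(out) == 1
        assert len(out[0]) == len(incomplete25.data) - incomplete25.n_incomplete


class TestSplineBasis:
    def test_linear_when_fewer_than_three_knots(self):
        x = np.linspace(0, 1, 20)
        assert rcs_basis(x, np.array([0.5])).shape == (20, 1)

    def test_three_knots_gives_two_columns(self):
        x = np.linspace(0, 10, 50)
        b = rcs_basis(x, np.array([1.0, 5.0, 9.0]))
        assert b.shape == (50, 2)

    def test_linear_beyond_boundary_knots(self):
        knots = np.array([2.0, 5.0, 8.0])
        x = np.array([9.0, 10.0, 11.0, 12.0])
        b = rcs_basis(x, knots)
        # second differences of every basis column vanish outside the knots
        d2 = np.diff(b, n=2, axis=0)
        assert np.allclose(d2, 0.0, atol=1e-9)

    def test_spline_nests_linear_fit(self, rng):
        # a linear truth is reproduced exactly by OLS on the rcs basis
        x = rng.uniform(0, 10, 200)
        y = 2.0 + 3.0 * x
        b = np.column_stack([np.ones_like(x), rcs_basis(x, np.array([2.0, 5.0, 8.0]))])
        coef, *_ = np.linalg.lstsq(b, y, rcond=None)
        assert np.allclose(b @ coef, y, atol=1e-8)
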