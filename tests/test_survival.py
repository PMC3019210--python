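import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coxmiss.population import km_survival_at
from coxmiss.survival import (
    KAPPA,
    breslow_cumhaz,
    cox_fit_matrix,
    fit_cox,
    nagelkerke_r2,
    nelson_aalen_at,
    predicted_survival,
    royston_d,
)

lifelines = pytest.importorskip("lifelines")
from lifelines import CoxPHFitter  # noqa: E402


def _random_survival_frame(rng, n=120, p=3, ties=False):
    x = rng.standard_normal((n, p))
    beta = rng.uniform(-0.8, 0.8, p)
    t = rng.exponential(scale=np.exp(-x @ beta))
    c = rng.exponential(scale=np.median(t) * 2, size=n)
    time = np.minimum(t, c)
    if ties:
        time = np.round(time, 1) + 0.05
    event = (t <= c).astype(int)
    if event.sum() == 0:
        event[0] = 1
    df = pd.DataFrame(x, columns=[f"x{i}" for i in range(p)])
    df["time"] = time
    df["event"] = event
    return df


def _lifelines_fit(df, cols):
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event",
            fit_options={"precision": 1e-10})
    return (cph.params_[cols].to_numpy(), cph.standard_errors_[cols].to_numpy(),
            cph.log_likelihood_)


class TestCoxFit:
    @pytest.mark.parametrize("seed,ties", [(0, False), (1, True), (2, False), (3, True)])
    def test_matches_reference_implementation(self, seed, ties):
        rng = np.random.default_rng(seed)
        df = _random_survival_frame(rng, ties=ties)
        cols = [c for c in df.columns if c.startswith("x")]
        fit = cox_fit_matrix(df[cols].to_numpy(), df["time"].to_numpy(),
                             df["event"].to_numpy(), names=tuple(cols))
        ref_b, ref_se, ref_ll = _lifelines_fit(df, cols)
        np.testing.assert_allclose(fit.beta, ref_b, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref_se, atol=1e-6)
        assert fit.loglik == pytest.approx(ref_ll, abs=1e-6)

    def test_null_covariate_coefficient_near_zero(self, population):
        df = population.head(4000).copy()
        rng = np.random.default_rng(0)
        df["noise"] = rng.standard_normal(len(df))
        fit = cox_fit_matrix(
            df[["noise"]].to_numpy(), df["time"].to_numpy(), df["event"].to_numpy()
        )
        assert abs(fit.beta[0] / fit.se[0]) < 3.5

    def test_two_group_exponential_closed_form(self):
        # exponential MLE oracle: beta = log(rate ratio)
        rng = np.random.default_rng(42)
        n = 4000
        g = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(scale=1.0 / np.where(g == 1, 2.0, 1.0))
        fit = cox_fit_matrix(g[:, None], t, np.ones(n, dtype=int))
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=3 * fit.se[0])

    def test_invariants(self, sample1000):
        fit = fit_cox(sample1000)
        assert fit.converged
        assert fit.loglik >= fit.loglik_null
        assert np.allclose(fit.vcov, fit.vcov.T, atol=1e-12)
        assert np.linalg.eigvalsh(fit.vcov).min() > 0
        np.testing.assert_allclose(fit.se, np.sqrt(np.diag(fit.vcov)))

    def test_significance_ordering_default_population(self, population):
        fit = fit_cox(population)
        p = dict(zip(fit.names, fit.p_values()))
        assert p["stage"] < 0.05 and p["age"] < 0.05
        assert p["site"] > 0.05 and p["ct_sch"] > 0.05

    def test_requires_events(self, sample1000):
        df = sample1000.copy()
        df["event"] = 0
        with pytest.raises(ValueError, match="event"):
            fit_cox(df)


class TestNagelkerke:
    def _fake_fit(self, n, l0, l1):
        fit = fit_cox.__wrapped__ if hasattr(fit_cox, "__wrapped__") else None
        from coxmiss.survival import CoxFitResult

        return CoxFitResult(
            beta=np.zeros(1), se=np.ones(1), vcov=np.eye(1),
            loglik_null=l0, loglik=l1, linear_predictor=np.zeros(n),
            n=n, n_events=n // 2, converged=True, names=("x",),
        )

    def test_zero_when_no_improvement(self):
        assert nagelkerke_r2(self._fake_fit(50, -100.0, -100.0)) == pytest.approx(0.0)

    def test_hand_formula(self):
        # n=100, l0=-300, l1=-290
        r2_cs = 1 - np.exp(-0.2)
        expected = r2_cs / (1 - np.exp(-6.0))
        assert nagelkerke_r2(self._fake_fit(100, -300.0, -290.0)) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_l1(self):
        vals = [nagelkerke_r2(self._fake_fit(100, -300.0, l1)) for l1 in (-295, -290, -280)]
        assert vals[0] < vals[1] < vals[2]

    def test_error_when_null_loglik_zero(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(self._fake_fit(10, 0.0, 0.0))


class TestRoystonD:
    def test_constant_predictor_is_zero(self, toy_survival):
        lp = np.zeros(len(toy_survival))
        assert royston_d(lp, toy_survival["time"], toy_survival["event"]) == 0.0

    def test_null_predictor_near_zero(self, sample1000):
        rng = np.random.default_rng(8)
        lp = rng.standard_normal(len(sample1000))
        d = royston_d(lp, sample1000["time"], sample1000["event"])
        assert abs(d) < 0.2

    def test_oracle_equivalence(self, sample1000):
        """Independently coded two-step oracle: rank transform + lifelines."""
        fit = fit_cox(sample1000)
        d = royston_d(fit.linear_predictor, sample1000["time"], sample1000["event"])
        n = len(sample1000)
        r = stats.rankdata(fit.linear_predictor)
        z = stats.norm.ppf((r - 0.375) / (n + 0.25)) / KAPPA
        df = pd.DataFrame({"z": z, "time": sample1000["time"], "event": sample1000["event"]})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-12})
        assert d == pytest.approx(float(cph.params_["z"]), abs=1e-8)

    def test_scale_invariance_of_linear_predictor(self, sample1000):
        fit = fit_cox(sample1000)
        t, e = sample1000["time"], sample1000["event"]
        d1 = royston_d(fit.linear_predictor, t, e)
        d2 = royston_d(3.0 * fit.linear_predictor + 5.0, t, e)
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestPredictedSurvival:
    def test_t_zero_is_one(self, sample1000):
        assert predicted_survival(fit_cox(sample1000), 0.0) == 1.0

    def test_null_model_matches_breslow_estimate(self, sample1000):
        df = sample1000.copy()
        rng = np.random.default_rng(5)
        df["noise"] = rng.standard_normal(len(df))  # ~null covariate
        fit = cox_fit_matrix(np.zeros((len(df), 1)), df["time"].to_numpy(),
                             df["event"].to_numpy())
        # with beta = 0 the prediction reduces to exp(-H0_NelsonAalen(t))
        s5 = predicted_survival(fit, 5.0)
        km = km_survival_at(df["time"], df["event"], 5.0)
        assert s5 == pytest.approx(km, abs=0.01)

    def test_non_increasing_in_t(self, sample1000):
        fit = fit_cox(sample1000)
        ts = [1.0, 2.0, 4.0, 6.0]
        vals = [predicted_survival(fit, t) for t in ts]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_extrapolation_error(self, sample1000):
        fit = fit_cox(sample1000)
        with pytest.raises(ValueError, match="beyond"):
            predicted_survival(fit, sample1000["time"].max() + 1.0)


class TestNelsonAalen:
    def test_monotone_in_time(self, sample1000):
        haz = nelson_aalen_at(sample1000["time"].to_numpy(), sample1000["event"].to_numpy())
        order = np.argsort(sample1000["time"].to_numpy())
        assert (np.diff(haz[order]) >= -1e-12).all()

    def test_hand_values(self):
        # times 1,2,3 all events: H(1)=1/3, H(2)=1/3+1/2, H(3)=...+1
        haz = nelson_aalen_at(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        np.testing.assert_allclose(haz, [1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2 + 1])
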