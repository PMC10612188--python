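"""Weibull AFT maximum likelihood, hazard-ratio conversion, LRT machinery."""

import numpy as np
import pandas as pd
import pytest

from glyvar.aft import (
    AFTFit,
    ConvergenceError,
    HazardRatio,
    RankDeficientDesignError,
    SurvivalDesign,
    aft_to_hr,
    build_design,
    fit_weibull_aft,
    lrt,
    stratified_treatment_hr,
)
from oracles import person_years_rate_ratio


def simulate_aft(n, beta, sigma, seed, censor=None, X=None):
    """Draw from log T = X beta + sigma W, W standard Gumbel (minimum)."""
    rng = np.random.default_rng(seed)
    if X is None:
        X = np.column_stack([np.ones(n), rng.normal(size=n), (rng.random(n) < 0.5)])
    W = np.log(rng.exponential(size=n))
    T = np.exp(X @ beta + sigma * W)
    if censor is None:
        t, d = T, np.ones(n, int)
    else:
        C = rng.uniform(*censor, n)
        t, d = np.minimum(T, C), (T <= C).astype(int)
    return X, t, d


def design_of(X, t, d, names=None):
    names = names or tuple(["Intercept"] + [f"x{i}" for i in range(1, X.shape[1])])
    return SurvivalDesign(t, d, X, names)


class TestFit:
    def test_sigma_recovery_no_covariates(self):
        # Weibull(shape 2) times: sigma = 1/shape = 0.5
        rng = np.random.default_rng(1)
        t = rng.weibull(2.0, 10_000)
        d = np.ones(10_000, int)
        fit = fit_weibull_aft(design_of(np.ones((10_000, 1)), t, d, ("Intercept",)))
        se_logs = np.sqrt(fit.cov[-1, -1])
        assert abs(np.log(fit.sigma) - np.log(0.5)) < 3 * se_logs

    def test_exponential_intercept_only(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(4.0, 10_000)
        d = np.ones(10_000, int)
        fit = fit_weibull_aft(design_of(np.ones((10_000, 1)), t, d, ("Intercept",)))
        assert abs(fit.sigma - 1.0) < 3 * np.sqrt(fit.cov[-1, -1])
        se_b = np.sqrt(fit.cov[0, 0])
        assert abs(fit.beta.iloc[0] - np.log(4.0)) < 3 * se_b

    def test_beta_recovery_within_3se(self):
        beta = np.array([1.0, 0.5, -0.7])
        X, t, d = simulate_aft(10_000, beta, 0.8, seed=3, censor=(0.5, 20))
        fit = fit_weibull_aft(design_of(X, t, d))
        for j in range(3):
            se = np.sqrt(fit.cov[j, j])
            assert abs(fit.beta.iloc[j] - beta[j]) < 3 * se
        assert abs(np.log(fit.sigma) - np.log(0.8)) < 3 * np.sqrt(fit.cov[-1, -1])

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        X, t, d = simulate_aft(800, np.array([0.8, 0.4, -0.3]), 0.7, seed=4, censor=(1, 10))
        fit = fit_weibull_aft(design_of(X, t, d))
        df = pd.DataFrame({"t": t, "d": d, "x1": X[:, 1], "x2": X[:, 2]})
        wf = lifelines.WeibullAFTFitter().fit(df, "t", "d", formula="x1 + x2")
        assert fit.loglik == pytest.approx(wf.log_likelihood_, abs=1e-4)
        ll_params = wf.params_["lambda_"]
        assert fit.beta["x1"] == pytest.approx(ll_params["x1"], abs=1e-5)
        assert fit.beta["x2"] == pytest.approx(ll_params["x2"], abs=1e-5)
        assert fit.sigma == pytest.approx(
            1.0 / np.exp(wf.params_["rho_"]["Intercept"]), abs=1e-5
        )

    def test_gradient_small_at_optimum(self):
        X, t, d = simulate_aft(2000, np.array([1.0, 0.3, -0.2]), 0.9, seed=5, censor=(1, 9))
        fit = fit_weibull_aft(design_of(X, t, d))
        assert fit.converged
        assert fit.grad_norm < 1e-6

    def test_aic_bic_identities(self):
        X, t, d = simulate_aft(500, np.array([1.0, 0.2, 0.1]), 1.1, seed=6)
        fit = fit_weibull_aft(design_of(X, t, d))
        p = len(fit.beta) + 1
        assert fit.aic == pytest.approx(2 * p - 2 * fit.loglik)
        assert fit.bic == pytest.approx(p * np.log(fit.n) - 2 * fit.loglik)

    def test_rank_deficiency_names_columns(self):
        X, t, d = simulate_aft(200, np.array([1.0, 0.2, 0.1]), 1.0, seed=7)
        X = np.column_stack([X, X[:, 1] * 2.0])
        with pytest.raises(RankDeficientDesignError, match="x3"):
            fit_weibull_aft(design_of(X, t, d, ("Intercept", "x1", "x2", "x3")))

    def test_rescaling_invariance(self):
        X, t, d = simulate_aft(3000, np.array([1.0, 0.4, -0.5]), 0.8, seed=8, censor=(1, 12))
        fit1 = fit_weibull_aft(design_of(X, t, d))
        X2 = X.copy()
        X2[:, 1] = X2[:, 1] * 100.0 + 50.0  # affine rescale of a covariate
        fit2 = fit_weibull_aft(design_of(X2, t, d))
        hr1 = aft_to_hr(fit1, "x1")
        hr2 = aft_to_hr(fit2, "x1", scale=100.0)
        assert hr1.hr == pytest.approx(hr2.hr, abs=1e-6)
        assert hr1.ci_low == pytest.approx(hr2.ci_low, rel=1e-4)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            SurvivalDesign(np.ones(5), np.zeros(5, int), np.ones((5, 1)), ("Intercept",))


class TestHazardRatio:
    def test_zero_coefficient_gives_unit_hr(self):
        fit = AFTFit(
            beta=pd.Series({"Intercept": 1.0, "x": 0.0}),
            sigma=0.7,
            loglik=0.0,
            cov=np.eye(3) * 0.01,
            n=100,
            n_events=50,
            converged=True,
        )
        assert aft_to_hr(fit, "x").hr == pytest.approx(1.0)

    def test_direct_formula(self):
        fit = AFTFit(
            beta=pd.Series({"x": -0.5}),
            sigma=1.0,
            loglik=0.0,
            cov=np.eye(2) * 0.01,
            n=100,
            n_events=50,
            converged=True,
        )
        assert aft_to_hr(fit, "x").hr == pytest.approx(np.exp(0.5))

    def test_unknown_term(self):
        fit = AFTFit(
            beta=pd.Series({"x": 0.0}), sigma=1.0, loglik=0.0,
            cov=np.eye(2), n=10, n_events=5, converged=True,
        )
        with pytest.raises(KeyError):
            aft_to_hr(fit, "nope")

    def test_nonconverged_refused(self):
        fit = AFTFit(
            beta=pd.Series({"x": 0.0}), sigma=1.0, loglik=0.0,
            cov=np.eye(2), n=10, n_events=5, converged=False,
        )
        with pytest.raises(ConvergenceError):
            aft_to_hr(fit, "x")

    def test_true_hr2_recovered(self):
        # Weibull PH with shape 1.5 and treatment log-HR = log 2
        rng = np.random.default_rng(9)
        n = 10_000
        treat = (rng.random(n) < 0.5).astype(float)
        shape = 1.5
        lp = np.log(0.10) + np.log(2.0) * treat
        T = (rng.exponential(size=n) * np.exp(-lp)) ** (1 / shape)
        C = np.full(n, 5.0)
        t, d = np.minimum(T, C), (T <= C).astype(int)
        X = np.column_stack([np.ones(n), treat])
        fit = fit_weibull_aft(design_of(X, t, d, ("Intercept", "treatment")))
        hr = aft_to_hr(fit, "treatment")
        assert 1.8 <= hr.hr <= 2.2
        assert hr.ci_low <= hr.hr <= hr.ci_high

    def test_hr_matches_person_years_ratio_for_exponential(self):
        rng = np.random.default_rng(10)
        n = 20_000
        treat = (rng.random(n) < 0.5).astype(float)
        lp = np.log(0.08) + np.log(1.8) * treat
        T = rng.exponential(size=n) * np.exp(-lp)
        C = np.full(n, 5.0)
        t, d = np.minimum(T, C), (T <= C).astype(int)
        X = np.column_stack([np.ones(n), treat])
        fit = fit_weibull_aft(design_of(X, t, d, ("Intercept", "treatment")))
        hr = aft_to_hr(fit, "treatment")
        crude = person_years_rate_ratio(t, d, treat.astype(bool))
        assert hr.hr == pytest.approx(crude, rel=0.05)

    def test_zero_effect_ci_coverage(self):
        covered = 0
        reps = 100
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            n = 600
            treat = (rng.random(n) < 0.5).astype(float)
            T = (rng.exponential(size=n) / 0.15) ** (1 / 1.2)
            C = np.full(n, 5.0)
            t, d = np.minimum(T, C), (T <= C).astype(int)
            X = np.column_stack([np.ones(n), treat])
            fit = fit_weibull_aft(design_of(X, t, d, ("Intercept", "treatment")))
            hr = aft_to_hr(fit, "treatment")
            covered += hr.ci_low <= 1.0 <= hr.ci_high
        assert covered >= 90


class TestLRT:
    def _data(self, n=400, seed=11):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x_null = rng.normal(size=n)
        W = np.log(rng.exponential(size=n))
        T = np.exp(1.0 + 0.5 * x1 + 0.8 * W)
        C = rng.uniform(1, 15, n)
        t, d = np.minimum(T, C), (T <= C).astype(int)
        return x1, x_null, t, d

    def _fit(self, n=400, seed=11, extra_null_col=False):
        x1, x_null, t, d = self._data(n, seed)
        cols, names = [np.ones(n), x1], ["Intercept", "x1"]
        if extra_null_col:
            cols.append(x_null)
            names.append("x_null")
        return fit_weibull_aft(design_of(np.column_stack(cols), t, d, tuple(names)))

    def test_identical_models_p_one(self):
        f = self._fit()
        assert lrt(f, f, df=1) == pytest.approx(1.0)

    def test_chi2_quantile(self):
        from scipy import stats

        f = self._fit()
        r = self._fit()
        r.loglik = f.loglik - 3.84 / 2
        assert lrt(f, r, df=1) == pytest.approx(stats.chi2.sf(3.84, 1), abs=1e-12)

    def test_full_loglik_never_below_reduced(self):
        full = self._fit(extra_null_col=True)
        reduced = self._fit()
        assert full.loglik >= reduced.loglik - 1e-8
        p = lrt(full, reduced, df=1)
        assert 0.0 <= p <= 1.0

    def test_nonnested_rejected(self):
        f = self._fit()
        other = self._fit(extra_null_col=True)
        with pytest.raises(ValueError, match="nested"):
            lrt(f, other, df=1)

    def test_bad_df(self):
        f = self._fit()
        with pytest.raises(ValueError):
            lrt(f, f, df=0)

    def test_null_interaction_type1_error(self):
        """2-df interaction LRT keeps its nominal size under the null."""
        rejections = 0
        reps = 200
        for r in range(reps):
            rng = np.random.default_rng(5000 + r)
            n = 900
            treat = (rng.random(n) < 0.5).astype(float)
            grp = rng.integers(0, 3, n)
            g1, g2 = (grp == 1).astype(float), (grp == 2).astype(float)
            lp = np.log(0.12) + 0.3 * treat - 0.2 * g1 + 0.25 * g2  # no interaction
            T = (rng.exponential(size=n) * np.exp(-lp)) ** (1 / 1.2)
            C = np.full(n, 5.0)
            t, d = np.minimum(T, C), (T <= C).astype(int)
            base = [np.ones(n), treat, g1, g2]
            full = fit_weibull_aft(
                design_of(
                    np.column_stack(base + [treat * g1, treat * g2]), t, d,
                    ("Intercept", "treat", "g1", "g2", "tx1", "tx2"),
                )
            )
            reduced = fit_weibull_aft(
                design_of(np.column_stack(base), t, d, ("Intercept", "treat", "g1", "g2"))
            )
            rejections += lrt(full, reduced, df=2) < 0.05
        assert 0.01 <= rejections / reps <= 0.10


class TestStratified:
    def test_empty_cell_error(self):
        rng = np.random.default_rng(12)
        n = 90
        df = pd.DataFrame(
            {
                "arm": ["standard"] * 30 + ["intensive", "standard"] * 30,
                "time_mace": rng.uniform(0.5, 5, n),
                "event_mace": rng.integers(0, 2, n),
            }
        )
        groups = np.array(["low"] * 30 + ["medium", "medium"] * 15 + ["high"] * 30)
        with pytest.raises(ValueError, match="low"):
            stratified_treatment_hr(df, groups, "mace", [])

    def test_build_design_dummy_coding(self):
        df = pd.DataFrame(
            {
                "time_mace": [1.0, 2.0, 3.0],
                "event_mace": [1, 0, 1],
                "race": ["a", "b", "c"],
                "age": [60.0, 61.0, 62.0],
            }
        )
        d = build_design(df, "time_mace", "event_mace", ["age", "race"])
        assert d.names == ("Intercept", "age", "race[b]", "race[c]")
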