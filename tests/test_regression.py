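"""Country-level regression: listwise deletion, robust OLS and logistic ML."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from ndchealth.regression import (
    COVARIATE_COLUMNS,
    fit_logistic,
    fit_ols_robust,
    listwise_complete,
    mcfadden_pseudo_r2,
)
from ndchealth.synthetic import SyntheticCovariateSpec, gen_covariates


def _records(n, rng, missing_idx=(), missing_col="democracy"):
    table, _ = gen_covariates(
        SyntheticCovariateSpec(n_countries=n, missing_rate=0.0),
        seed=int(rng.integers(2**31 - 1)),
    )
    cov = table.drop(columns=["any_mention", "hes", "htp"])
    cov.loc[list(missing_idx), missing_col] = np.nan
    out = table[["iso3", "any_mention", "hes", "htp"]]
    return cov, out


class TestListwise:
    def test_two_incomplete_rows_dropped_and_reported(self):
        rng = np.random.default_rng(0)
        cov, out = _records(10, rng, missing_idx=[1, 4])
        data, dropped = listwise_complete(cov, out)
        assert len(data) == 8
        assert dropped == sorted(cov.loc[[1, 4], "iso3"])

    def test_complete_table_is_identity(self):
        rng = np.random.default_rng(1)
        cov, out = _records(10, rng)
        data, dropped = listwise_complete(cov, out)
        assert len(data) == 10 and dropped == []

    def test_fewer_than_two_rows_is_an_error(self):
        rng = np.random.default_rng(2)
        cov, out = _records(3, rng, missing_idx=[0, 1])
        with pytest.raises(ValueError, match="fewer than 2"):
            listwise_complete(cov, out)

    def test_planted_missingness_pattern_recovered(self):
        spec = SyntheticCovariateSpec(n_countries=60, missing_rate=0.2)
        table, _ = gen_covariates(spec, seed=11)
        cov = table.drop(columns=["any_mention", "hes", "htp"])
        out = table[["iso3", "any_mention", "hes", "htp"]]
        data, dropped = listwise_complete(cov, out)
        expected_dropped = sorted(table.loc[table["democracy"].isna(), "iso3"])
        assert dropped == expected_dropped


class TestOlsRobust:
    def test_noiseless_fit_is_exact(self):
        x = np.linspace(0, 10, 50)
        data = pd.DataFrame({"x": x, "y": 2.0 * x})
        res = fit_ols_robust(data, "y", covariates=["x"])
        assert res.params["x"] == pytest.approx(2.0)
        assert res.bse["x"] == pytest.approx(0.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0)

    def test_coefficients_identical_across_covariance_choices(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame({"x": rng.normal(size=200)})
        data["y"] = 1.0 + 0.5 * data["x"] + rng.normal(size=200)
        robust = fit_ols_robust(data, "y", covariates=["x"], hc_type="HC1")
        classical = fit_ols_robust(data, "y", covariates=["x"], hc_type="nonrobust")
        assert robust.params.equals(classical.params)
        assert not robust.bse.equals(classical.bse)

    def test_hc1_approaches_classical_under_homoscedasticity(self):
        rng = np.random.default_rng(4)
        n = 5000
        data = pd.DataFrame({"x": rng.normal(size=n)})
        data["y"] = 2.0 + 1.0 * data["x"] + rng.normal(size=n)
        hc1 = fit_ols_robust(data, "y", covariates=["x"], hc_type="HC1")
        cls = fit_ols_robust(data, "y", covariates=["x"], hc_type="nonrobust")
        ratio = hc1.bse["x"] / cls.bse["x"]
        assert 0.9 < ratio < 1.1

    def test_rank_deficiency_names_collinear_column(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame({"x": rng.normal(size=30)})
        data["x2"] = 2.0 * data["x"]
        data["y"] = data["x"] + rng.normal(size=30)
        with pytest.raises(ValueError, match="x2"):
            fit_ols_robust(data, "y", covariates=["x", "x2"])

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame({"x": rng.normal(size=100)})
        data["y"] = 0.3 * data["x"] + rng.normal(size=100)
        res = fit_ols_robust(data, "y", covariates=["x"])
        assert (res.ci_low <= res.params).all() and (res.params <= res.ci_high).all()


class TestLogistic:
    def test_single_class_outcome_rejected(self):
        data = pd.DataFrame({"x": np.arange(10.0), "y": np.ones(10)})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(data, "y", covariates=["x"])

    def test_non_binary_outcome_rejected(self):
        data = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(data, "y", covariates=["x"])

    def test_perfect_separation_is_a_hard_error(self):
        x = np.arange(8.0)
        data = pd.DataFrame({"x": x, "y": (x > 3.5).astype(float)})
        with pytest.raises(ValueError, match="separation"):
            fit_logistic(data, "y", covariates=["x"])

    def test_matches_gradient_free_likelihood_maximization(self):
        """Cross-check: Nelder–Mead maximisation of the Bernoulli likelihood
        agrees with the fitted coefficients to 4 decimals on a 30-row fixture."""
        rng = np.random.default_rng(7)
        n = 30
        data = pd.DataFrame({
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
        })
        eta = 0.3 + 1.2 * data["x1"] - 0.8 * data["x2"]
        data["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = fit_logistic(data, "y", covariates=["x1", "x2"])

        X = np.column_stack([np.ones(n), data["x1"], data["x2"]])
        y = data["y"].to_numpy()

        def negll(beta):
            e = X @ beta
            return -np.sum(y * e - np.log1p(np.exp(e)))

        opt = minimize(negll, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert res.params.to_numpy() == pytest.approx(opt.x, abs=1e-4)

    def test_null_covariate_ci_covers_zero_at_nominal_rate(self):
        """With an outcome independent of one covariate, its Wald 95% CI
        should cover zero in at least 93 of 100 seeded replicates (n=5000)."""
        rng = np.random.default_rng(8)
        n = 5000
        covered = 0
        for _ in range(100):
            x = rng.normal(size=n)
            noise = rng.normal(size=n)  # unrelated to the outcome
            eta = 0.2 + 0.8 * x
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            data = pd.DataFrame({"x": x, "z": noise, "y": y})
            res = fit_logistic(data, "y", covariates=["x", "z"])
            if res.ci_low["z"] <= 0 <= res.ci_high["z"]:
                covered += 1
        assert covered >= 93


class TestPseudoR2:
    def test_balanced_intercept_only_is_zero(self):
        import statsmodels.api as sm

        y = np.array([0.0, 1.0] * 20)
        X = np.ones((40, 1))
        res = sm.Logit(y, X).fit(disp=False)
        assert mcfadden_pseudo_r2(res) == pytest.approx(0.0, abs=1e-9)

    def test_strong_signal_band(self):
        rng = np.random.default_rng(9)
        n = 2000
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-4.0 * x))).astype(float)
        data = pd.DataFrame({"x": x, "y": y})
        res = fit_logistic(data, "y", covariates=["x"])
        assert 0.5 < res.pseudo_r2 < 0.9

    def test_reported_in_unit_interval(self):
        rng = np.random.default_rng(10)
        n = 500
        data = pd.DataFrame({"x": rng.normal(size=n)})
        data["y"] = (rng.random(n) < 0.5).astype(float)
        res = fit_logistic(data, "y", covariates=["x"])
        assert 0 <= res.pseudo_r2 < 1

    def test_summary_contains_fit_statistic(self):
        rng = np.random.default_rng(11)
        n = 300
        data = pd.DataFrame({"x": rng.normal(size=n)})
        data["y"] = (rng.random(n) < 1 / (1 + np.exp(-data["x"]))).astype(float)
        res = fit_logistic(data, "y", covariates=["x"])
        assert "pseudo-R2" in res.summary()
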