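import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from healtheq import (
    average_marginal_effects,
    decompose_index,
    elasticity,
    erreygers_index,
    fit_logit,
    fractional_rank,
    generate,
    calibrate_to_paper,
    percentage_contribution,
)
from healtheq.concentration import weighted_cov, weighted_mean
from healtheq.decomposition import LogitFit


def _logit(p):
    return np.log(p / (1 - p))


class TestFitLogit:
    def test_intercept_only_recovers_weighted_prevalence(self, rng):
        h = (rng.random(500) < 0.3).astype(int)
        w = rng.uniform(0.5, 3, size=500)
        fit = fit_logit(h, pd.DataFrame(index=range(500)), w)
        mu = weighted_mean(h, w)
        assert fit.params["intercept"] == pytest.approx(_logit(mu), abs=1e-8)
        # score equation: weighted mean of fitted probabilities = weighted prevalence
        assert weighted_mean(fit.fitted, w) == pytest.approx(mu, abs=1e-8)

    def test_single_binary_covariate_is_weighted_log_odds_ratio(self, rng):
        n = 400
        x = (rng.random(n) < 0.5).astype(float)
        p = np.where(x == 1, 0.4, 0.2)
        h = (rng.random(n) < p).astype(int)
        w = rng.uniform(0.5, 2, size=n)
        fit = fit_logit(h, pd.DataFrame({"x": x}), w)
        # closed form from the weighted 2x2 table
        cells = {
            (i, j): w[(x == i) & (h == j)].sum() for i in (0, 1) for j in (0, 1)
        }
        lor = np.log(cells[1, 1] * cells[0, 0] / (cells[1, 0] * cells[0, 1]))
        assert fit.params["x"] == pytest.approx(lor, abs=1e-6)

    def test_weights_equal_duplicated_rows(self, rng):
        n = 120
        x = (rng.random(n) < 0.5).astype(float)
        h = (rng.random(n) < 0.2 + 0.3 * x).astype(int)
        reps = rng.integers(1, 4, size=n)
        fit_w = fit_logit(h, pd.DataFrame({"x": x}), reps.astype(float))
        idx = np.repeat(np.arange(n), reps)
        fit_d = fit_logit(h[idx], pd.DataFrame({"x": x[idx]}), np.ones(len(idx)))
        assert fit_w.params["x"] == pytest.approx(fit_d.params["x"], abs=1e-8)
        assert fit_w.params["intercept"] == pytest.approx(fit_d.params["intercept"], abs=1e-8)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logit(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}), np.ones(10))

    def test_collinear_column_dropped_with_warning(self, rng):
        x = (rng.random(100) < 0.5).astype(float)
        h = (rng.random(100) < 0.2 + 0.3 * x).astype(int)
        X = pd.DataFrame({"x": x, "x_copy": 1.0 - x})  # collinear with x + intercept
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_logit(h, X, np.ones(100))
        assert len(fit.dropped) == 1

    def test_separation_warning(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        h = x.astype(int)
        with pytest.warns(UserWarning, match="separation"):
            fit_logit(h, pd.DataFrame({"x": x}), np.ones(40))


class TestAverageMarginalEffects:
    def test_single_binary_closed_form_prevalence_difference(self, rng):
        n = 600
        x = (rng.random(n) < 0.4).astype(float)
        h = (rng.random(n) < 0.15 + 0.25 * x).astype(int)
        w = rng.uniform(0.5, 2, size=n)
        fit = fit_logit(h, pd.DataFrame({"x": x}), w)
        ame = average_marginal_effects(fit, pd.DataFrame({"x": x}), w)
        p1 = weighted_mean(h[x == 1], w[x == 1])
        p0 = weighted_mean(h[x == 0], w[x == 0])
        assert ame["x"] == pytest.approx(p1 - p0, abs=1e-6)

    def test_zero_coefficient_zero_ame(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]})
        fit = LogitFit(
            params=pd.Series({"intercept": -1.0, "x": 0.0}),
            fitted=np.full(4, 0.269),
            converged=True,
            iterations=1,
            loglik=0.0,
            columns=["x"],
        )
        ame = average_marginal_effects(fit, X, np.ones(4))
        assert ame["x"] == 0.0

    def test_continuous_ame_is_mean_density_times_beta(self, rng):
        n = 500
        z = rng.normal(size=n)
        h = (rng.random(n) < 1 / (1 + np.exp(-(-1 + 0.8 * z)))).astype(int)
        w = np.ones(n)
        fit = fit_logit(h, pd.DataFrame({"z": z}), w)
        ame = average_marginal_effects(fit, pd.DataFrame({"z": z}), w)
        p = fit.fitted
        assert ame["z"] == pytest.approx(np.mean(p * (1 - p)) * fit.params["z"], abs=1e-10)

    def test_cross_check_against_statsmodels_margeff(self, rng):
        """Independent route: statsmodels' discrete-change margins."""
        n = 800
        x1 = (rng.random(n) < 0.4).astype(float)
        x2 = (rng.random(n) < 0.6).astype(float)
        h = (rng.random(n) < 1 / (1 + np.exp(-(-1.2 + 0.7 * x1 + 0.4 * x2)))).astype(int)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        fit = fit_logit(h, X, np.ones(n))
        ame = average_marginal_effects(fit, X, np.ones(n))
        sm_fit = sm.Logit(h, sm.add_constant(X)).fit(disp=0)
        sm_ame = sm_fit.get_margeff(at="overall", method="dydx", dummy=True).margeff
        np.testing.assert_allclose(ame[["x1", "x2"]].to_numpy(), sm_ame, atol=1e-5)


class TestDecomposeIndex:
    @pytest.fixture(scope="class")
    def fitted_round(self):
        from dataclasses import replace
        from healtheq import encode_design

        cfg = calibrate_to_paper(2016)
        table, _ = generate(replace(cfg, clusters_per_stratum=40), seed=11)  # n = 7,200
        df = table.data
        w = df["weight"].to_numpy()
        design, _ = encode_design(df, table.covariates)
        fit = fit_logit(df["h"].to_numpy(), design, w)
        ranks = fractional_rank(df["wealth_score"].to_numpy(), w)
        E = erreygers_index(df["h"].to_numpy(), ranks, w).E
        dec = decompose_index(E, fit, design, ranks, w, table.covariates)
        return design, w, ranks, fit, dec

    def test_adding_up_is_exact(self, fitted_round):
        _, _, _, _, dec = fitted_round
        assert dec.table["contribution"].sum() + dec.residual == pytest.approx(dec.E, abs=1e-12)

    def test_contribution_identity_8_beta_cov(self, fitted_round):
        design, w, ranks, fit, dec = fitted_round
        ames = average_marginal_effects(fit, design, w)
        for col in dec.table.index:
            a_direct = 8.0 * ames[col] * weighted_cov(design[col].to_numpy(), ranks, w)
            assert dec.table.loc[col, "contribution"] == pytest.approx(a_direct, abs=1e-10)

    def test_percentages_sum_to_explained_share(self, fitted_round):
        _, _, _, _, dec = fitted_round
        assert dec.total_percent_explained == pytest.approx(
            100 * (dec.E - dec.residual) / dec.E, abs=1e-8
        )
        assert dec.group_percent.sum() == pytest.approx(dec.total_percent_explained, abs=1e-8)

    def test_rank_independent_covariate_contributes_nothing(self, rng):
        """A covariate with zero concentration index (C_k = 0) contributes
        a_k = 0 regardless of its marginal effect."""
        n = 2000
        x = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        score = np.r_[np.arange(n // 2), np.arange(n // 2)]  # x balanced at every rank
        w = np.ones(n)
        h = (rng.random(n) < 0.15 + 0.4 * x).astype(int)
        X = pd.DataFrame({"x": x})
        fit = fit_logit(h, X, w)
        ranks = fractional_rank(score, w)
        E = erreygers_index(h, ranks, w).E
        if abs(E) < 1e-6:
            E = 0.01  # decomposition needs a nonzero total; contribution is still ~0
        dec = decompose_index(E, fit, X, ranks, w)
        assert dec.table.loc["x", "ci_k"] == pytest.approx(0.0, abs=1e-12)
        assert dec.table.loc["x", "contribution"] == pytest.approx(0.0, abs=1e-12)

    def test_tiny_total_index_rejected(self, rng):
        X = pd.DataFrame({"x": [0.0, 1.0] * 10})
        h = np.array([0, 1] * 10)
        fit = fit_logit(h, X, np.ones(20))
        with pytest.raises(ValueError, match="undefined"):
            decompose_index(1e-9, fit, X, np.linspace(0.1, 0.9, 20), np.ones(20))


class TestPrintedArithmetic:
    """The elasticity/contribution conventions reproduce published accounting."""

    def test_erreygers_scale_elasticity(self):
        assert elasticity(0.065, 0.3668) == pytest.approx(0.0954, abs=5e-4)

    def test_percentage_contribution_television(self):
        assert percentage_contribution(0.096, 0.507, 0.201) == pytest.approx(24.2, abs=0.05)
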