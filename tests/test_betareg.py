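import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from lekid.betareg import (
    BetaRegression,
    CollinearityError,
    NotConvergedError,
    backward_select,
    scaled_residuals,
    squeeze_to_open_interval,
)


def simulate_beta(rng, X, beta, phi):
    mu = expit(X @ np.asarray(beta))
    return rng.beta(mu * phi, (1 - mu) * phi)


def direct_loglike(y, X, beta, phi):
    """Oracle: term-by-term beta log-density from the definition."""
    total = 0.0
    for yi, xi in zip(y, X):
        mu = 1.0 / (1.0 + math.exp(-float(np.dot(xi, beta))))
        a, b = mu * phi, (1 - mu) * phi
        total += (math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
                  + (a - 1) * math.log(yi) + (b - 1) * math.log(1 - yi))
    return total


class TestSqueeze:
    @pytest.mark.parametrize("y, n, expected", [
        (0.0, 10, 0.05), (1.0, 10, 0.95), (0.5, 10, 0.5), (0.5, 1000, 0.5),
    ])
    def test_formula(self, y, n, expected):
        assert squeeze_to_open_interval([y], n)[0] == pytest.approx(expected)

    def test_strictly_interior_and_order_preserving(self):
        y = np.linspace(0, 1, 11)
        z = squeeze_to_open_interval(y)
        assert np.all((z > 0) & (z < 1))
        assert np.all(np.diff(z) > 0)

    @pytest.mark.parametrize("bad", [[-0.1], [1.1], [np.nan]])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            squeeze_to_open_interval(bad, 10)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            squeeze_to_open_interval([0.5], 1)


class TestLikelihood:
    def test_matches_direct_summation_at_random_points(self):
        rng = np.random.default_rng(0)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.uniform(0.05, 0.95, size=n)
        model = BetaRegression(y, X)
        for _ in range(100):
            beta = rng.normal(scale=1.5, size=2)
            phi = float(rng.uniform(0.5, 60))
            assert model.loglike(beta, phi) == pytest.approx(
                direct_loglike(y, X, beta, phi), abs=1e-10 * n)

    def test_optimum_beats_grid_search(self):
        """MLE log-likelihood >= every point of a 21x21 (intercept, log phi) grid."""
        rng = np.random.default_rng(1)
        n = 200
        X = np.ones((n, 1))
        y = simulate_beta(rng, X, [-0.4], 12.0)
        fit = BetaRegression(y, X, ["const"]).fit()
        b_hat, logphi_hat = fit.params["const"], math.log(fit.phi)
        model = BetaRegression(y, X, ["const"])
        grid_best = -np.inf
        for b in np.linspace(b_hat - 0.5, b_hat + 0.5, 21):
            for lp in np.linspace(logphi_hat - 0.7, logphi_hat + 0.7, 21):
                grid_best = max(grid_best, model.loglike([b], math.exp(lp)))
        assert fit.llf >= grid_best - 1e-8


class TestFit:
    def test_intercept_only_recovery(self):
        rng = np.random.default_rng(2)
        n = 2000
        X = np.ones((n, 1))
        y = simulate_beta(rng, X, [logit(0.3)], 20.0)
        fit = BetaRegression(y, X, ["const"]).fit()
        assert fit.converged
        assert abs(fit.params["const"] - logit(0.3)) < 3 * fit.bse["const"]
        assert fit.phi == pytest.approx(20.0, rel=0.15)

    def test_binary_covariate_recovery(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        X = np.column_stack([np.ones(n), x])
        y = simulate_beta(rng, X, [-0.5, 1.0], 15.0)
        fit = BetaRegression(y, X, ["const", "x"]).fit()
        assert 0.8 < fit.params["x"] < 1.2

    def test_agrees_with_independent_implementation(self):
        """Cross-check estimates and llf against statsmodels' beta model."""
        from statsmodels.othermod.betareg import BetaModel

        rng = np.random.default_rng(4)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = simulate_beta(rng, X, [0.2, -0.7], 8.0)
        ours = BetaRegression(y, X, ["const", "x"]).fit()
        theirs = BetaModel(y, X).fit(disp=0)
        assert ours.llf == pytest.approx(theirs.llf, abs=1e-5)
        np.testing.assert_allclose(ours.params.to_numpy(), theirs.params[:2],
                                   atol=1e-4)

    def test_high_precision_limit_recovers_sample_mean(self):
        """As phi grows the fitted mean approaches the sample mean."""
        rng = np.random.default_rng(5)
        n = 500
        X = np.ones((n, 1))
        y = simulate_beta(rng, X, [0.3], 5000.0)
        fit = BetaRegression(y, X, ["const"]).fit()
        assert expit(fit.params["const"]) == pytest.approx(y.mean(), abs=1e-2)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        with pytest.raises(CollinearityError):
            BetaRegression(rng.uniform(0.2, 0.8, 50), X)

    def test_boundary_endog_rejected(self):
        with pytest.raises(ValueError, match="squeeze"):
            BetaRegression([0.0, 0.5, 1.0], np.ones((3, 1)))

    def test_from_formula_with_categorical(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame({
            "y": rng.uniform(0.1, 0.9, 120),
            "g": rng.choice(["marks", "form"], 120),
        })
        fit = BetaRegression.from_formula("y ~ C(g)", data).fit()
        assert "C(g)[T.marks]" in fit.params.index
        assert np.all((fit.predict() > 0) & (fit.predict() < 1))

    def test_wald_inference_shapes(self):
        rng = np.random.default_rng(8)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        fit = BetaRegression(simulate_beta(rng, X, [0.0, 0.5], 10.0), X).fit()
        assert fit.pvalues.between(0, 1).all()
        np.testing.assert_allclose(fit.zvalues, fit.params / fit.bse)
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * (2 + 1))
        ci = fit.conf_int()
        assert (ci["lower"] < fit.params).all() and (fit.params < ci["upper"]).all()

    def test_summary_mentions_key_quantities(self):
        rng = np.random.default_rng(9)
        X = np.ones((100, 1))
        fit = BetaRegression(simulate_beta(rng, X, [0.0], 10.0), X,
                             response_name="RI").fit()
        text = fit.summary()
        assert "RI" in text and "AIC" in text and "phi" in text


class TestBackwardSelect:
    @staticmethod
    def _selection_data(rng, n=300, effects=(0.0, 0.0, 0.0, 0.0), phi=15.0):
        data = pd.DataFrame({
            f"x{i}": (rng.random(n) < 0.5).astype(float) for i in range(4)})
        eta = -0.3 + sum(e * data[f"x{i}"] for i, e in enumerate(effects))
        mu = expit(eta)
        data["y"] = rng.beta(mu * phi, (1 - mu) * phi)
        return data

    def test_single_strong_candidate_gives_two_row_table(self):
        rng = np.random.default_rng(10)
        n = 400
        x = (rng.random(n) < 0.5).astype(float)
        mu = expit(-1.0 + 2.5 * x)
        data = pd.DataFrame({"x": x, "y": rng.beta(mu * 20, (1 - mu) * 20)})
        table = backward_select(data, "y", ["x"])
        assert len(table.frame) == 2
        assert table.best_formula == "y ~ x"
        assert table.frame.loc[0, "formula"] == "y ~ x"

    def test_weights_and_delta_invariants(self):
        rng = np.random.default_rng(11)
        data = self._selection_data(rng, effects=(1.0, 0.0, 0.0, 0.0))
        table = backward_select(data, "y", [f"x{i}" for i in range(4)])
        assert table.frame["weight"].sum() == pytest.approx(1.0)
        assert (table.frame["weight"] >= 0).all()
        assert (table.frame["delta_aic"] >= 0).all()
        assert table.frame.loc[0, "delta_aic"] == 0.0
        assert table.best_formula in table.retained  # best model always retained

    def test_true_effect_survives_selection(self):
        rng = np.random.default_rng(12)
        data = self._selection_data(rng, effects=(1.0, 0.0, 0.0, 0.0))
        table = backward_select(data, "y", [f"x{i}" for i in range(4)])
        assert "x0" in table.best_formula

    def test_all_subsets_visits_every_model(self):
        rng = np.random.default_rng(13)
        data = self._selection_data(rng, n=150)
        table = backward_select(data, "y", ["x0", "x1"], mode="all_subsets")
        assert len(table.frame) == 4  # 2^2 subsets
        assert table.frame["aic"].min() == table.fits[table.best_formula].aic

    def test_adding_noise_term_never_lowers_loglik(self):
        """Nested-model sanity: the full model's llf >= any submodel's."""
        rng = np.random.default_rng(14)
        data = self._selection_data(rng, n=200, effects=(0.8, 0.0, 0.0, 0.0))
        table = backward_select(data, "y", ["x0", "x1"], mode="all_subsets")
        llf = {f: r.llf for f, r in table.fits.items()}
        assert llf["y ~ x0 + x1"] >= llf["y ~ x0"] - 1e-6
        assert llf["y ~ x0"] >= llf["y ~ 1"] - 1e-6


class TestScaledResiduals:
    @staticmethod
    def _fit(rng, n=200):
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = simulate_beta(rng, X, [0.2, 0.6], 12.0)
        return BetaRegression(y, X).fit()

    def test_residuals_in_unit_interval_and_ks_fields(self):
        rng = np.random.default_rng(15)
        fit = self._fit(rng)
        diag = scaled_residuals(fit, n_simulations=100, rng=rng)
        assert np.all((diag.scaled_residuals >= 0) & (diag.scaled_residuals <= 1))
        assert 0 <= diag.uniformity_p <= 1
        assert diag.n_simulations == 100

    def test_extreme_observation_hits_one(self):
        rng = np.random.default_rng(16)
        fit = self._fit(rng)
        y = np.full(fit.nobs, 1 - 1e-12)  # above every plausible simulation
        diag = scaled_residuals(fit, y=y, n_simulations=50, rng=rng)
        assert np.all(diag.scaled_residuals == 1.0)

    def test_single_simulation_granularity(self):
        rng = np.random.default_rng(17)
        fit = self._fit(rng)
        diag = scaled_residuals(fit, n_simulations=1, rng=rng)
        assert set(np.unique(diag.scaled_residuals)) <= {0.0, 1.0}

    def test_refuses_nonconverged_fit(self):
        rng = np.random.default_rng(18)
        fit = self._fit(rng)
        fit.converged = False
        with pytest.raises(NotConvergedError):
            scaled_residuals(fit, rng=rng)

    def test_well_specified_model_is_calibrated(self):
        rng = np.random.default_rng(19)
        fit = self._fit(rng, n=300)
        y_new = fit.simulate(rng, 1)[0]
        diag = scaled_residuals(fit, y=y_new, n_simulations=200, rng=rng)
        assert diag.uniformity_p > 0.01
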