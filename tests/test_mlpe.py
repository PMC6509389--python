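import numpy as np
import pytest

from samplescape import DistanceMatrix
from samplescape.mlpe import (
    CandidateModel,
    build_response_design,
    fit_candidates,
    information_criteria,
    mlpe_fit,
    rank_models,
    _pair_incidence,
)


def dm_from_vec(vec, labels, metric="dps_distance"):
    n = len(labels)
    m = np.zeros((n, n))
    m[np.tril_indices(n, -1)] = vec
    return DistanceMatrix(labels, m + m.T, metric, "population")


def simulate_mlpe(n_sites, beta, sigma_u2, sigma_e2, rng, x=None):
    Z = _pair_incidence(n_sites)
    n = Z.shape[0]
    if x is None:
        x = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    u = rng.normal(0, np.sqrt(sigma_u2), n_sites)
    y = X @ np.asarray(beta) + Z @ u + rng.normal(0, np.sqrt(sigma_e2), n)
    return y, X, Z


def dense_grid_loglik(y, X, Z, method, phi_grid):
    """Brute-force oracle: explicit V, direct inverse, grid over phi.

    ML evaluates the multivariate-normal density literally via scipy;
    REML uses the textbook restricted likelihood
    -0.5 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py ].
    """
    from scipy.stats import multivariate_normal

    n, p = X.shape
    M = Z @ Z.T
    best = -np.inf
    for phi in phi_grid:
        W = np.eye(n) + phi * M
        Wi = np.linalg.inv(W)
        beta = np.linalg.solve(X.T @ Wi @ X, X.T @ Wi @ y)
        r = y - X @ beta
        rss = r @ Wi @ r
        if method == "ML":
            s2 = rss / n
            V = s2 * W
            ll = multivariate_normal.logpdf(y, mean=X @ beta, cov=V)
        else:
            s2 = rss / (n - p)
            V = s2 * W
            Vi = np.linalg.inv(V)
            _, logdet_v = np.linalg.slogdet(V)
            _, logdet_x = np.linalg.slogdet(X.T @ Vi @ X)
            P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
            ll = -0.5 * (
                (n - p) * np.log(2 * np.pi)
                + logdet_v + logdet_x + y @ P @ y
            )
        best = max(best, ll)
    return best


class TestDesign:
    def _toy(self, P, seed=0):
        rng = np.random.default_rng(seed)
        n = P * (P - 1) // 2
        labels = [f"s{k}" for k in range(P)]
        y = dm_from_vec(rng.random(n), labels)
        pred = {"res": dm_from_vec(rng.random(n), labels,
                                   "effective_resistance")}
        return y, pred

    @pytest.mark.parametrize("P,rows", [(3, 3), (18, 153), (40, 780)])
    def test_row_counts(self, P, rows):
        y, pred = self._toy(P)
        model = CandidateModel("res", ["res"])
        yv, X, Z, pairs = build_response_design(y, pred, model)
        assert len(yv) == rows and X.shape == (rows, 2)
        assert Z.shape == (rows, P)
        assert (Z.sum(axis=1) == 2).all()
        assert len(pairs) == rows

    def test_standardized_columns(self):
        y, pred = self._toy(6)
        _, X, _, _ = build_response_design(
            y, pred, CandidateModel("res", ["res"])
        )
        assert X[:, 1].mean() == pytest.approx(0, abs=1e-12)
        assert X[:, 1].std(ddof=1) == pytest.approx(1)

    def test_label_mismatch_error(self):
        y, pred = self._toy(4)
        bad = {"res": dm_from_vec(np.ones(3), ["a", "b", "c"])}
        with pytest.raises(ValueError):
            build_response_design(y, bad, CandidateModel("res", ["res"]))

    def test_k_convention(self):
        assert CandidateModel("distance", ["distance"]).k == 4
        assert CandidateModel("full", ["a", "b", "c", "d"]).k == 7


class TestFit:
    def test_no_population_effect_recovers_ols(self):
        rng = np.random.default_rng(1)
        y, X, Z = simulate_mlpe(12, [0.3, 0.2], 0.0, 0.01, rng)
        fit = mlpe_fit(y, X, Z, "ML")
        bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
        # OLS standard errors
        resid = y - X @ bhat
        s2 = resid @ resid / (len(y) - 2)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(fit.beta - bhat) < 2 * se)
        assert fit.sigma_u2 < 0.05 * fit.sigma_e2

    def test_zeroed_incidence_equals_ols_exactly(self):
        rng = np.random.default_rng(2)
        y, X, Z = simulate_mlpe(8, [0.5, -0.2], 0.02, 0.01, rng)
        fit = mlpe_fit(y, X, np.zeros_like(Z), "ML")
        bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.beta, bhat, atol=1e-10)
        assert fit.phi == 0.0

    @pytest.mark.parametrize("method", ["ML", "REML"])
    @pytest.mark.parametrize("P", [4, 6, 8])
    def test_matches_dense_grid_oracle(self, method, P):
        """Maximized profile likelihood matches a dense MVN grid search."""
        rng = np.random.default_rng(100 + P)
        y, X, Z = simulate_mlpe(P, [0.4, 0.25], 0.02, 0.01, rng)
        fit = mlpe_fit(y, X, Z, method)
        # stage 1: fine linear grid to 10 plus coarse log grid beyond
        grid = np.concatenate(
            [np.arange(0.0, 10.0, 1e-3), np.logspace(1, 3, 400)]
        )
        lls = [dense_grid_loglik(y, X, Z, method, [g]) for g in grid]
        best = int(np.argmax(lls))
        # stage 2: refine around the coarse optimum
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        fine = np.linspace(lo, hi, 2000)
        oracle = dense_grid_loglik(y, X, Z, method, fine)
        # optimizer should do at least as well as the refined grid
        assert fit.loglik >= oracle - 1e-6
        assert fit.loglik == pytest.approx(oracle, abs=1e-3)

    def test_constant_response_boundary(self):
        Z = _pair_incidence(5)
        n = Z.shape[0]
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        fit = mlpe_fit(np.full(n, 0.7), X, Z, "ML")
        assert abs(fit.beta[1]) < 1e-8
        assert fit.sigma_e2 >= 0

    def test_reml_invariant_to_response_shift(self):
        rng = np.random.default_rng(4)
        y, X, Z = simulate_mlpe(7, [0.2, 0.3], 0.01, 0.02, rng)
        f1 = mlpe_fit(y, X, Z, "REML")
        f2 = mlpe_fit(y + 5.0, X, Z, "REML")
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_rank_deficient_design_error(self):
        Z = _pair_incidence(5)
        n = Z.shape[0]
        X = np.ones((n, 2))
        with pytest.raises(np.linalg.LinAlgError):
            mlpe_fit(np.arange(n, dtype=float), X, Z, "ML")

    def test_parameter_recovery_monte_carlo(self):
        """Estimates from the MLPE generative model are unbiased within
        3 Monte-Carlo standard errors (18 sites, 200 replicates)."""
        rng = np.random.default_rng(77)
        beta_true = np.array([0.5, 0.3])
        su2, se2 = 0.005, 0.01
        est = []
        for _ in range(200):
            y, X, Z = simulate_mlpe(18, beta_true, su2, se2, rng)
            fit = mlpe_fit(y, X, Z, "REML")
            est.append([*fit.beta, fit.sigma_u2, fit.sigma_e2])
        est = np.array(est)
        mean = est.mean(axis=0)
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        truth = np.array([*beta_true, su2, se2])
        assert np.all(np.abs(mean - truth) < 3 * mc_se)


class TestInformationCriteria:
    def test_hand_arithmetic(self):
        aicc, bic = information_criteria(-10.0, 4, 153)
        assert aicc == pytest.approx(28 + 40 / 148, abs=1e-5)
        assert bic == pytest.approx(20 + 4 * np.log(153), abs=1e-5)

    def test_aicc_approaches_aic(self):
        a1, _ = information_criteria(-10.0, 4, 100)
        a2, _ = information_criteria(-10.0, 4, 100_000)
        aic = 28.0
        assert a2 - aic < a1 - aic
        assert a2 == pytest.approx(aic, abs=1e-3)

    def test_fewer_parameters_win_at_equal_likelihood(self):
        a3, b3 = information_criteria(-10.0, 3, 50)
        a4, b4 = information_criteria(-10.0, 4, 50)
        assert a3 < a4 and b3 < b4

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            information_criteria(-10.0, 10, 11)


class TestRankModels:
    def test_single_model(self):
        df = rank_models({"m": (100.0, 105.0, 4)})
        assert df.loc["m", "dAICc"] == 0
        assert df.loc["m", "wAICc"] == pytest.approx(1.0)

    def test_two_model_weights(self):
        df = rank_models({"a": (100.0, 100.0, 4), "b": (102.0, 102.0, 4)})
        assert df.loc["a", "wAICc"] == pytest.approx(1 / (1 + np.exp(-1)),
                                                     abs=1e-3)
        assert df.loc["b", "wAICc"] == pytest.approx(
            np.exp(-1) / (1 + np.exp(-1)), abs=1e-3
        )
        assert df["wAICc"].sum() == pytest.approx(1.0, abs=1e-10)
        assert df["wBIC"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_order_invariance(self):
        crit = {"a": (10.0, 11.0, 4), "b": (12.0, 12.0, 5), "c": (9.0, 13.0, 4)}
        d1 = rank_models(crit)
        d2 = rank_models(dict(reversed(list(crit.items()))))
        import pandas.testing as pdt
        pdt.assert_frame_equal(d1.sort_index(), d2.sort_index())

    def test_tie_broken_by_smaller_k(self):
        df = rank_models({"big": (10.0, 10.0, 6), "small": (10.0, 10.0, 4)})
        assert df.loc["small", "rank"] == 1
        assert df.loc["big", "rank"] == 2


class TestFitCandidates:
    def test_end_to_end_ranking(self):
        rng = np.random.default_rng(5)
        P = 10
        labels = [f"s{k}" for k in range(P)]
        n = P * (P - 1) // 2
        x_true = rng.standard_normal(n)
        x_noise = rng.standard_normal(n)
        Z = _pair_incidence(P)
        u = rng.normal(0, 0.05, P)
        y = 0.3 * x_true + Z @ u + rng.normal(0, 0.05, n)
        resp = dm_from_vec(y - y.min() + 0.1, labels)
        preds = {
            "true": dm_from_vec(x_true, labels, "effective_resistance"),
            "noise": dm_from_vec(x_noise, labels, "effective_resistance"),
        }
        models = [CandidateModel("true", ["true"]),
                  CandidateModel("noise", ["noise"])]
        for method in ("ML", "REML"):
            tbl, fits = fit_candidates(resp, preds, models, method=method)
            assert tbl.loc["true", "dAICc"] == 0.0
            assert fits["true"].converged
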