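import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from nncopula import (SimulationDesign, TwoPL, eap_score, gh_quadrature,
                      infit_outfit, simulate_2pl, two_pl_probability)


class TestQuadrature:
    def test_weights_normalised(self):
        _, w = gh_quadrature(61)
        assert abs(w.sum() - 1.0) < 1e-10

    def test_matches_normal_moments(self):
        t, w = gh_quadrature(61)
        assert abs(np.sum(w * t)) < 1e-10
        assert abs(np.sum(w * t**2) - 1.0) < 1e-6


class TestFit:
    def test_parameter_recovery(self, small_sim):
        # large-sample recovery is the acceptance-level check; here a
        # moderate dataset must still rank-order the items correctly
        Y, truth, _ = small_sim
        res = TwoPL(Y).fit()
        assert res.converged
        assert np.corrcoef(truth["b"], res.b)[0, 1] > 0.9

    def test_em_loglik_monotone(self, small_sim):
        res = TwoPL(small_sim[0]).fit()
        assert np.all(np.diff(res.loglik_trace) > -1e-8)

    def test_column_permutation_equivariance(self, small_sim):
        Y = small_sim[0]
        perm = [3, 1, 4, 0, 2, 9, 7, 5, 8, 6]
        res = TwoPL(Y).fit()
        res_p = TwoPL(Y.iloc[:, perm]).fit()
        np.testing.assert_allclose(res_p.a, res.a[perm], atol=1e-8)
        np.testing.assert_allclose(res_p.b, res.b[perm], atol=1e-8)

    def test_row_duplication_invariance_and_se_scaling(self, small_sim):
        Y = small_sim[0]
        Y2 = pd.concat([Y, Y], ignore_index=True)
        res = TwoPL(Y).fit()
        res2 = TwoPL(Y2).fit()
        np.testing.assert_allclose(res2.a, res.a, atol=1e-6)
        np.testing.assert_allclose(res2.b, res.b, atol=1e-6)
        np.testing.assert_allclose(res2.se.to_numpy(),
                                   res.se.to_numpy() / np.sqrt(2), rtol=1e-6)

    def test_degenerate_item_is_named(self):
        Y = pd.DataFrame({"ok": [0, 1] * 150, "allone": [1] * 300})
        with pytest.raises(ValueError, match="allone"):
            TwoPL(Y)

    def test_nonconvergence_is_flagged_not_raised(self, small_sim):
        with pytest.warns(UserWarning, match="did not converge"):
            res = TwoPL(small_sim[0]).fit(tol=1e-12, max_cycles=2)
        assert not res.converged

    def test_summary_mentions_fit_facts(self, small_sim):
        res = TwoPL(small_sim[0]).fit()
        text = res.summary()
        assert "log-likelihood" in text and "item01" in text


@pytest.fixture(scope="module")
def params():
    rng = np.random.default_rng(2)
    return rng.uniform(0.6, 2.5, 12), rng.normal(size=12)


class TestEAP:

    def test_extreme_patterns_finite(self, params):
        a, b = params
        t, w = gh_quadrature()
        theta, sd = eap_score(np.vstack([np.zeros(12), np.ones(12)]), a, b, t, w)
        assert np.isfinite(theta).all() and np.isfinite(sd).all()

    def test_symmetric_test_negates(self):
        a = np.full(8, 1.4)
        b = np.array([-1.5, -1.0, -0.5, -0.1, 0.1, 0.5, 1.0, 1.5])
        t, w = gh_quadrature()
        y = np.array([1, 1, 0, 1, 0, 1, 0, 0])
        th1, _ = eap_score(y[None, :], a, b, t, w)
        th2, _ = eap_score((1 - y)[::-1][None, :], a, b, t, w)
        assert th1[0] == pytest.approx(-th2[0], abs=1e-8)

    def test_agreement_with_dense_grid_integration(self, params):
        a, b = params
        rng = np.random.default_rng(8)
        Y = rng.integers(0, 2, size=(50, 12))
        t, w = gh_quadrature()
        eap_q, _ = eap_score(Y, a, b, t, w)
        grid = np.linspace(-8, 8, 10001)
        logit = a[None, :] * (grid[:, None] - b[None, :])
        ll = Y @ (-np.logaddexp(0, -logit)).T + (1 - Y) @ (-np.logaddexp(0, logit)).T
        post = np.exp(ll) * norm.pdf(grid)[None, :]
        dense = np.trapezoid(post * grid[None, :], grid, axis=1) / \
            np.trapezoid(post, grid, axis=1)
        assert np.max(np.abs(eap_q - dense)) < 1e-4

    def test_shrinkage_bounds(self, params):
        a, b = params
        t, w = gh_quadrature()
        rng = np.random.default_rng(1)
        Y = rng.integers(0, 2, size=(200, 12))
        theta, sd = eap_score(Y, a, b, t, w)
        assert np.max(np.abs(theta)) <= np.max(np.abs(t))
        assert np.all(sd <= 1.0 + 1e-6)  # proper N(0,1) prior shrinks


class TestStandardErrors:
    def test_se_increases_with_discrimination(self, benchmark_sim, reference_fit):
        # steep items are estimated with larger absolute SE(a)
        from scipy.stats import spearmanr
        rho = spearmanr(reference_fit.a, reference_fit.se["se_a"]).statistic
        assert rho > 0

    def test_information_matrix_matches_derivative_oracle(self, small_sim):
        """The per-item 2x2 information equals the negative Hessian (finite
        differences) of the posterior-weighted expected log-likelihood with
        expected counts."""
        res = TwoPL(small_sim[0]).fit()
        n_q = res.posterior.sum(axis=0)
        theta = res.model.theta_q
        info = res.fisher_information()

        def expected_ll(k, a, b):
            P = 1 / (1 + np.exp(-a * (theta - b)))
            P_hat = 1 / (1 + np.exp(-res.a[k] * (theta - res.b[k])))
            return np.sum(n_q * (P_hat * np.log(P) + (1 - P_hat) * np.log1p(-P)))

        eps = 1e-4
        for k in (0, 3, 7):
            a0, b0 = res.a[k], res.b[k]
            H = np.empty((2, 2))
            for i, (da, db) in enumerate(((eps, 0.0), (0.0, eps))):
                for j, (ea, eb) in enumerate(((eps, 0.0), (0.0, eps))):
                    H[i, j] = (expected_ll(k, a0 + da + ea, b0 + db + eb)
                               - expected_ll(k, a0 + da - ea, b0 + db - eb)
                               - expected_ll(k, a0 - da + ea, b0 - db + eb)
                               + expected_ll(k, a0 - da - ea, b0 - db - eb)
                               ) / (4 * eps * eps)
            np.testing.assert_allclose(info[k], -H, rtol=1e-4, atol=1e-6)

    def test_asymptotic_se_tracks_sampling_sd_from_below(self):
        """Block-diagonal expected-information SEs track, and slightly
        understate, the Monte-Carlo SD of the MML estimator (the missing-
        information principle: complete-data information is an upper bound)."""
        rng = np.random.default_rng(0)
        a = rng.uniform(0.7, 1.8, 10)
        b = rng.uniform(-1.5, 1.5, 10)
        est_a, est_b = [], []
        for s in range(60):
            Y, _, _ = simulate_2pl(SimulationDesign(n=3244, K=10, a=a, b=b,
                                                    seed=1000 + s))
            res = TwoPL(Y).fit()
            est_a.append(res.a)
            est_b.append(res.b)
        mc_sd_a = np.vstack(est_a).std(axis=0, ddof=1)
        mc_sd_b = np.vstack(est_b).std(axis=0, ddof=1)
        Y, _, _ = simulate_2pl(SimulationDesign(n=3244, K=10, a=a, b=b, seed=7))
        se = TwoPL(Y).fit().se
        for ratio in (se["se_a"] / mc_sd_a, se["se_b"] / mc_sd_b):
            assert np.all(ratio > 0.5) and np.all(ratio < 1.1)
            assert 0.65 < ratio.mean() < 1.0


class TestFitStatistics:
    def test_self_consistent_data_near_one(self):
        # responses drawn exactly from the plug-in model probabilities
        rng = np.random.default_rng(3)
        n, K = 20000, 10
        a = rng.uniform(0.7, 2.2, K)
        b = rng.normal(size=K)
        theta = rng.standard_normal(n)
        P = two_pl_probability(theta[:, None], a[None, :], b[None, :])
        Y = (rng.random((n, K)) < P).astype(int)
        stats = infit_outfit(Y, a, b, theta)
        assert np.all(stats["infit"].between(0.9, 1.1))
        assert np.all(stats["outfit"].between(0.9, 1.1))

    def test_deterministic_responses_underdispersed(self):
        theta = np.linspace(-3, 3, 5000)
        a = np.full(6, 1.5)
        b = np.linspace(-1.5, 1.5, 6)
        Y = (theta[:, None] > b[None, :]).astype(int)
        stats = infit_outfit(Y, a, b, theta)
        assert np.all(stats["outfit"] < 0.7)
        assert any("under-dispersion" in f for f in stats["flag"]
                   if f)  # severe cases flagged

    def test_flag_thresholds(self):
        # craft one item far too deterministic and one well-behaved
        rng = np.random.default_rng(9)
        theta = rng.standard_normal(8000)
        a = np.array([3.0, 1.0])
        b = np.zeros(2)
        P = two_pl_probability(theta[:, None], np.array([[1.0, 1.0]]), b[None, :])
        Y = np.column_stack([
            (theta > 0).astype(int),                       # deterministic
            (rng.random(8000) < P[:, 1]).astype(int),      # stochastic
        ])
        stats = infit_outfit(Y, a, b, theta)
        assert stats["outfit"].iloc[0] < 0.5
        assert "severe under-dispersion" in stats["flag"].iloc[0]
        assert stats["flag"].iloc[1] == ""
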