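import numpy as np
import pandas as pd
import pytest

from nncopula import RunConfig, TwoPL
from nncopula.validation import (dependence_facet, marginal_facet, mcse,
                                 psychometric_facet, recovery_metrics,
                                 score_distribution_summary,
                                 sensitivity_driver, stability_facet,
                                 validation_report)

from conftest import rng_binary


class TestScoreDistribution:
    def test_constant_rows_yield_null_shape(self):
        Y = np.ones((30, 5), dtype=int)
        out = score_distribution_summary(Y)
        assert out["sd"] == 0.0
        assert out["skewness"] is None and out["excess_kurtosis"] is None

    def test_symmetric_two_point_scores(self):
        Y = np.vstack([np.zeros((50, 6)), np.ones((50, 6))]).astype(int)
        out = score_distribution_summary(Y)
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert out["mean"] == pytest.approx(3.0)

    def test_gaussian_scores_have_zero_excess_kurtosis(self):
        # many weak items -> near-normal total scores
        Y = rng_binary(100000, 40, seed=0, p=0.5)
        out = score_distribution_summary(Y)
        assert abs(out["excess_kurtosis"]) < 0.05
        assert abs(out["skewness"]) < 0.05


class TestMarginalFacet:
    def test_identical_matrices(self):
        Y = rng_binary(500, 6, seed=1)
        out = marginal_facet(Y, Y, n_boot=50, seed=0)
        assert out["mad"] == 0.0
        assert out["mean_relative_pct"] == 0.0
        assert out["n_within_ci"] == 6

    def test_single_item_toy(self):
        Y_real = np.repeat([[1], [0]], [50, 50], axis=0)
        Y_syn = np.repeat([[1], [0]], [60, 40], axis=0)
        out = marginal_facet(Y_real, Y_syn, n_boot=50, seed=0)
        assert out["mad"] == pytest.approx(0.1, abs=1e-12)
        assert out["mean_relative_pct"] == pytest.approx(20.0, abs=1e-9)

    def test_item_count_mismatch(self):
        with pytest.raises(ValueError):
            marginal_facet(rng_binary(20, 3, 0), rng_binary(20, 4, 0))


class TestDependenceFacet:
    def test_identical_matrices(self):
        Y = rng_binary(300, 8, seed=2)
        assert dependence_facet(Y, Y) == 0.0

    def test_single_pair_value(self):
        # two 2-item datasets whose correlations differ by a known amount
        rng = np.random.default_rng(3)
        z = rng.standard_normal(20000)
        Y_real = np.column_stack([(z > 0), (z + rng.standard_normal(20000) > 0)])
        Y_syn = np.column_stack([(z > 0), rng.random(20000) > 0.5]).astype(int)
        delta = (np.corrcoef(Y_real, rowvar=False)[0, 1]
                 - np.corrcoef(Y_syn, rowvar=False)[0, 1])
        assert dependence_facet(Y_real.astype(int), Y_syn) == pytest.approx(
            abs(delta), abs=1e-12)

    def test_matches_double_loop_oracle(self):
        Y_real = rng_binary(400, 10, seed=4)
        Y_syn = rng_binary(400, 10, seed=5)
        Rr = np.corrcoef(Y_real, rowvar=False)
        Rs = np.corrcoef(Y_syn, rowvar=False)
        acc, cnt = 0.0, 0
        for k in range(10):
            for l in range(k + 1, 10):
                acc += (Rr[k, l] - Rs[k, l]) ** 2
                cnt += 1
        assert dependence_facet(Y_real, Y_syn) == pytest.approx(
            np.sqrt(acc / cnt), abs=1e-12)

    def test_constant_column_is_named(self):
        Y = rng_binary(50, 3, seed=6)
        Y_bad = Y.copy()
        Y_bad[:, 1] = 1
        with pytest.raises(ValueError, match="column 1"):
            dependence_facet(Y, Y_bad)


class TestRecoveryMetrics:
    def test_mad_never_exceeds_rmsd(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x, y = rng.normal(size=15), rng.normal(size=15)
            out = recovery_metrics(x, y)
            assert out["mad"] <= out["rmsd"] + 1e-12

    def test_identical_vectors_are_perfect(self):
        params = pd.DataFrame({"a": [1.0, 2.0, 1.5], "b": [-1.0, 0.0, 1.0]})
        out = psychometric_facet(params, params.copy())
        for key in ("a", "b"):
            assert out[key]["mad"] == 0.0 and out[key]["rmsd"] == 0.0
            assert out[key]["r"] == pytest.approx(1.0)
        assert out["tif_r"] == pytest.approx(1.0)
        assert out["csem_r"] == pytest.approx(1.0)


class TestMCSE:
    def test_degenerate_replications(self):
        est = np.tile([1.3, -0.2], (10, 1))
        np.testing.assert_allclose(mcse(est), [0.0, 0.0], atol=1e-12)

    def test_recovers_generating_sd(self):
        rng = np.random.default_rng(8)
        est = rng.normal(loc=2.0, scale=0.37, size=(10000, 1))
        assert mcse(est)[0] == pytest.approx(0.37, rel=0.02)

    def test_needs_two_replications(self):
        with pytest.raises(ValueError):
            mcse(np.array([[1.0, 2.0]]))


class TestPipelines:
    def test_validation_report_self_pair(self, small_sim):
        Y = small_sim[0]
        fit = TwoPL(Y).fit()
        rep = validation_report(Y, Y, fit, fit, n_boot=50, seed=0)
        assert rep["marginal"]["mad"] == 0.0
        assert rep["dependence_rmsr"] == 0.0
        assert rep["psychometric"]["b"]["r"] == pytest.approx(1.0)
        assert rep["fit_statistics"]["mean_abs_infit_diff"] == 0.0

    def test_stability_identical_seeds_zero_sd(self, small_sim, tiny_config):
        Y, truth, _ = small_sim
        table = stability_facet(Y.iloc[:480], Y.iloc[480:], truth,
                                tiny_config, seeds=(5, 5))
        sd_row = table.loc["sd"].astype(float).fillna(0.0)
        assert sd_row.max() == pytest.approx(0.0, abs=1e-12)

    def test_wide_bandwidth_oversmooths_dependence(self, benchmark_sim,
                                                   trained_generator):
        """The widest KDE bandwidth blurs the inter-item correlation
        structure: RMSR is largest at h = 0.5 among {0.1, 0.2, 0.5}."""
        from nncopula.kde import LatentKDE
        from nncopula.model import NeuralCopulaResults
        Y_train = benchmark_sim[0].to_numpy()
        res = trained_generator
        means = []
        for h in (0.1, 0.2, 0.5):
            clone = NeuralCopulaResults(
                network=res.network, kde=LatentKDE.fit(res.kde.codes, h),
                p_hat=res.p_hat, item_labels=res.item_labels,
                config=res.config, trace=res.trace, fit_seed=res.fit_seed)
            means.append(np.mean([
                dependence_facet(Y_train, clone.generate(3244, s).to_numpy())
                for s in range(5)]))
        assert means[2] == max(means)

    def test_sensitivity_smoke(self, small_sim, tiny_config):
        Y, truth, _ = small_sim
        table = sensitivity_driver(Y.iloc[:480], Y.iloc[480:], truth,
                                   d_grid=(3,), h_grid=(), M=2,
                                   master_seed=0, config=tiny_config)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["parameter"] == "latent_dim"
        for col in ("r_a", "r_b", "mad_marginal", "rmsr"):
            assert row[col] is None or np.isfinite(row[col])
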