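"""Structured least squares vs dense oracles, TF selection, diagnostics."""

import numpy as np
import pytest

from stagetf import (
    SimulationParams,
    build_design,
    fit_integrative,
    fit_tf_only,
    infer_tf_activity,
    residual_diagnostics,
    simulate_dataset,
)
from stagetf.errors import ValidationError
from stagetf.model import design_matrix, stacked_response

from conftest import make_dataset, make_tfmap


def dense_lstsq(dataset, tfmap, tf_only=False):
    X = design_matrix(dataset, tfmap, tf_only=tf_only).toarray()
    y = stacked_response(dataset)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X, y, beta


def flat_coefficients(fit):
    gene_part = np.stack([fit.beta_cn, fit.beta_me], axis=1).ravel()
    return np.concatenate([gene_part, fit.beta_tf])


class TestBuildDesign:
    def test_headline_dimensions(self):
        """5,684 genes x 178 samples with 206 TFs."""
        rng = np.random.default_rng(0)
        G, S, T = 5684, 178, 206
        ds = make_dataset(
            np.zeros((G, S)),
            np.full((G, S), 2.0),
            np.full((G, S), 0.3),
            ["I"] * 123 + ["IV"] * 55,
        )
        inc = (rng.random((T, G)) < 0.1).astype(np.int8)
        inc[:6] = 1  # ensure alignment contract (degree irrelevant here)
        spec = build_design(ds, make_tfmap(inc))
        assert spec.n_obs == 1_011_752
        assert spec.n_coef == 11_574

    def test_stage_gating(self):
        # one gene, one bound TF; stage-I rows have no TF contribution
        ds = make_dataset(
            [[1.0, 2, 3, 4]],
            [[2.0, 2, 2, 2]],
            [[0.3, 0.3, 0.4, 0.4]],
            ["I", "I", "IV", "IV"],
        )
        X = design_matrix(ds, make_tfmap([[1]])).toarray()
        # columns: cn, me, tf
        np.testing.assert_array_equal(X[:, 2], [0, 0, 1, 1])

    def test_nonzero_pattern_enumeration(self):
        rng = np.random.default_rng(18)
        G, S, T = 3, 4, 2
        stage = np.array(["I", "IV", "I", "IV"], dtype=object)
        inc = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
        ds = make_dataset(
            rng.normal(size=(G, S)),
            rng.normal(2, 0.3, (G, S)),
            rng.random((G, S)),
            stage,
        )
        X = design_matrix(ds, make_tfmap(inc)).toarray()
        for f in range(T):
            col = X[:, 2 * G + f]
            expected = np.zeros(G * S)
            for i in range(G):
                for j in range(S):
                    if inc[f, i] and stage[j] == "IV":
                        expected[i * S + j] = 1
            np.testing.assert_array_equal(col, expected)

    def test_gene_mismatch_rejected(self, small_sim):
        dataset, tfmap, _ = small_sim
        with pytest.raises(ValidationError, match="gene"):
            build_design(dataset.subset_genes(np.arange(10)), tfmap)


class TestFitIntegrative:
    def test_matches_dense_oracle(self):
        params = SimulationParams(
            n_genes=20, n_samples=12, n_tfs=3, min_tfs=2, noise_sd=0.3, seed=7
        )
        dataset, tfmap, _ = simulate_dataset(params)
        fit = fit_integrative(dataset, tfmap, method="ols")
        _, _, beta = dense_lstsq(dataset, tfmap)
        np.testing.assert_allclose(flat_coefficients(fit), beta, atol=1e-8)

    @pytest.mark.parametrize("seed", range(6))
    def test_dense_oracle_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        G = int(rng.integers(5, 50))
        S = int(rng.integers(8, 20))
        T = int(rng.integers(2, 10))
        params = SimulationParams(
            n_genes=G, n_samples=S, n_tfs=T, min_tfs=min(1, T - 1) or None,
            noise_sd=float(rng.uniform(0.1, 1.0)), seed=seed + 1000,
        )
        dataset, tfmap, _ = simulate_dataset(params)
        fit = fit_integrative(dataset, tfmap)
        _, _, beta = dense_lstsq(dataset, tfmap)
        np.testing.assert_allclose(flat_coefficients(fit), beta, atol=1e-8)

    def test_residual_orthogonality(self, small_sim):
        dataset, tfmap, _ = small_sim
        fit = fit_integrative(dataset, tfmap)
        X = design_matrix(dataset, tfmap)
        assert np.abs(X.T @ fit.residuals).max() < 1e-6

    def test_standard_errors_match_dense(self):
        params = SimulationParams(
            n_genes=15, n_samples=14, n_tfs=4, min_tfs=2, noise_sd=0.4, seed=23
        )
        dataset, tfmap, _ = simulate_dataset(params)
        fit = fit_integrative(dataset, tfmap)
        X, y, _ = dense_lstsq(dataset, tfmap)
        cov = fit.sigma2 * np.linalg.inv(X.T @ X)
        G = dataset.n_genes
        np.testing.assert_allclose(
            fit.se_tf, np.sqrt(np.diag(cov)[2 * G :]), rtol=1e-8
        )
        np.testing.assert_allclose(
            fit.se_cn, np.sqrt(np.diag(cov)[0 : 2 * G : 2]), rtol=1e-8
        )
        np.testing.assert_allclose(
            fit.se_me, np.sqrt(np.diag(cov)[1 : 2 * G : 2]), rtol=1e-8
        )

    def test_linearity_in_expression_scale(self, small_sim):
        dataset, tfmap, _ = small_sim
        fit1 = fit_integrative(dataset, tfmap)
        fit2 = fit_integrative(dataset.with_expression(2 * dataset.expression), tfmap)
        np.testing.assert_allclose(fit2.beta_tf, 2 * fit1.beta_tf, atol=1e-9)
        np.testing.assert_allclose(fit2.beta_cn, 2 * fit1.beta_cn, atol=1e-9)
        np.testing.assert_allclose(fit2.beta_me, 2 * fit1.beta_me, atol=1e-9)

    def test_ridge_shrinks_monotonically(self, small_sim):
        dataset, tfmap, _ = small_sim
        norms = []
        for lam in [0.0, 1.0, 10.0, 100.0, 1e4, 1e6]:
            fit = fit_integrative(dataset, tfmap, method="ridge", lam=lam)
            norms.append(np.linalg.norm(flat_coefficients(fit)))
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2 * norms[0]

    def test_ridge_matches_dense_closed_form(self):
        params = SimulationParams(
            n_genes=10, n_samples=10, n_tfs=3, min_tfs=2, noise_sd=0.5, seed=31
        )
        dataset, tfmap, _ = simulate_dataset(params)
        lam = 2.5
        fit = fit_integrative(dataset, tfmap, method="ridge", lam=lam)
        X, y, _ = dense_lstsq(dataset, tfmap)
        beta = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ y)
        np.testing.assert_allclose(flat_coefficients(fit), beta, atol=1e-8)

    def test_lasso_runs_and_shrinks(self, small_sim):
        dataset, tfmap, _ = small_sim
        ols = fit_integrative(dataset, tfmap)
        lasso = fit_integrative(dataset, tfmap, method="lasso", lam=0.5)
        assert lasso.method == "lasso"
        assert lasso.sse >= ols.sse
        n_zero = (np.abs(flat_coefficients(lasso)) < 1e-10).sum()
        assert n_zero > 0

    def test_singular_block_warns_and_falls_back(self):
        rng = np.random.default_rng(24)
        G, S = 3, 8
        cnv = rng.normal(2, 0.3, (G, S))
        meth = rng.random((G, S))
        meth[0] = 0.5 * cnv[0]  # proportional -> singular 2x2 block
        ds = make_dataset(rng.normal(size=(G, S)), cnv, meth,
                          ["I"] * 4 + ["IV"] * 4)
        tfmap = make_tfmap(np.array([[1, 1, 0], [0, 1, 1]], dtype=np.int8))
        with pytest.warns(RuntimeWarning, match="singular"):
            fit_integrative(ds, tfmap)
        with pytest.raises(np.linalg.LinAlgError):
            fit_integrative(ds, tfmap, strict=True)

    def test_unknown_method(self, small_sim):
        dataset, tfmap, _ = small_sim
        with pytest.raises(ValueError):
            fit_integrative(dataset, tfmap, method="elastic")


class TestFitTfOnly:
    def test_matches_dense_oracle(self, small_sim):
        dataset, tfmap, _ = small_sim
        fit = fit_tf_only(dataset, tfmap)
        _, _, beta = dense_lstsq(dataset, tfmap, tf_only=True)
        np.testing.assert_allclose(fit.beta_tf, beta, atol=1e-8)
        assert fit.beta_cn is None and fit.beta_me is None

    def test_nested_sse_ordering(self, small_sim):
        dataset, tfmap, _ = small_sim
        assert fit_integrative(dataset, tfmap).sse <= fit_tf_only(dataset, tfmap).sse

    def test_single_tf_closed_form(self):
        # all genes are targets, noiseless stage shift delta -> beta = delta
        delta = 1.7
        G, S = 5, 10
        stage = np.array(["I"] * 5 + ["IV"] * 5, dtype=object)
        expr = np.where(stage[None, :] == "IV", delta, 0.0) * np.ones((G, 1))
        ds = make_dataset(expr, np.full((G, S), 2.0), np.full((G, S), 0.3), stage)
        fit = fit_tf_only(ds, make_tfmap(np.ones((1, G), dtype=np.int8)))
        np.testing.assert_allclose(fit.beta_tf, [delta], atol=1e-10)
        np.testing.assert_allclose(fit.sse, 0.0, atol=1e-18)

    def test_agrees_with_integrative_when_no_covariate_effects(self):
        params = SimulationParams(
            n_genes=300, n_samples=100, n_tfs=10, min_tfs=3,
            beta_cn_dist=(0.0, 0.0), beta_me_dist=(0.0, 0.0),
            n_active_tfs=4, noise_sd=0.3, seed=41,
        )
        dataset, tfmap, _ = simulate_dataset(params)
        full = fit_integrative(dataset, tfmap)
        reduced = fit_tf_only(dataset, tfmap)
        assert np.all(np.abs(full.beta_tf - reduced.beta_tf) < 2 * full.se_tf + 2 * reduced.se_tf)


class TestInferTFActivity:
    def test_planted_tf_selected(self):
        params = SimulationParams(
            n_genes=500, n_samples=200, n_tfs=10, min_tfs=3, n_active_tfs=1,
            active_beta_magnitude=1.0, noise_sd=0.5, seed=51,
        )
        dataset, tfmap, truth = simulate_dataset(params)
        fit = fit_integrative(dataset, tfmap)
        table = infer_tf_activity(fit)
        active = tfmap.tf_ids[truth.true_beta_tf != 0]
        assert set(active) <= set(table.selected)

    def test_null_tfs_not_selected(self):
        params = SimulationParams(
            n_genes=400, n_samples=120, n_tfs=40, min_tfs=5, n_active_tfs=0,
            noise_sd=0.5, seed=52,
        )
        dataset, tfmap, _ = simulate_dataset(params)
        table = infer_tf_activity(fit_integrative(dataset, tfmap))
        assert len(table.selected) <= 1

    def test_effect_boundary_strict(self, small_sim):
        dataset, tfmap, _ = small_sim
        fit = fit_integrative(dataset, tfmap)
        fit.beta_tf = np.full_like(fit.beta_tf, 0.5)
        fit.se_tf = np.full_like(fit.se_tf, 1e-6)
        table = infer_tf_activity(fit, effect_threshold=0.5)
        assert len(table.selected) == 0

    def test_rejects_fit_without_se(self, small_sim):
        dataset, tfmap, _ = small_sim
        lasso = fit_integrative(dataset, tfmap, method="lasso", lam=0.1)
        with pytest.raises(ValidationError):
            infer_tf_activity(lasso)


class TestResidualDiagnostics:
    def test_normal_residuals_near_zero_moments(self, small_sim):
        dataset, tfmap, _ = small_sim
        fit = fit_integrative(dataset, tfmap)
        rng = np.random.default_rng(0)
        fit.residual_matrix = rng.normal(size=(1000, 100))
        fit.fitted = rng.normal(size=(1000, 100))
        diag = residual_diagnostics(fit)
        assert abs(diag["skewness"]) < 0.05
        assert abs(diag["excess_kurtosis"]) < 0.05

    def test_mirrored_residuals_zero_skew(self, small_sim):
        dataset, tfmap, _ = small_sim
        fit = fit_integrative(dataset, tfmap)
        rng = np.random.default_rng(1)
        half = rng.normal(size=500)
        sym = np.concatenate([half, -half])
        fit.residual_matrix = sym.reshape(20, 50)
        fit.fitted = rng.normal(size=(20, 50))
        diag = residual_diagnostics(fit)
        np.testing.assert_allclose(diag["skewness"], 0.0, atol=1e-12)

    def test_exponential_residuals_skew_two(self, small_sim):
        dataset, tfmap, _ = small_sim
        fit = fit_integrative(dataset, tfmap)
        rng = np.random.default_rng(2)
        fit.residual_matrix = rng.exponential(size=(1000, 100))
        fit.fitted = rng.normal(size=(1000, 100))
        diag = residual_diagnostics(fit)
        np.testing.assert_allclose(diag["skewness"], 2.0, atol=0.15)
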