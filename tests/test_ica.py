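"""PCA whitening, Infomax, group decompositions, dual regression."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from covnet.cohort import simulate_structural_cohort
from covnet.config import PipelineConfig
from covnet.ica import (
    decompose_functional,
    decompose_structural,
    dual_regression,
    flag_artifact_components,
    infomax_ica,
    pca_reduce,
    threshold_map,
    zscore_maps,
)


def best_match_r(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Optimal one-to-one |correlation| assignment between two map sets."""
    ka = maps_a.shape[0]
    C = np.abs(np.corrcoef(np.vstack([maps_a, maps_b]))[:ka, ka:])
    ri, ci = linear_sum_assignment(-C)
    return C[ri, ci]


class TestPcaReduce:
    def test_full_rank_reconstruction_exact(self, rng):
        X = rng.standard_normal((10, 3)) @ rng.standard_normal((3, 200))
        Xw = pca_reduce(X, 3)
        recon = Xw.dewhitening @ Xw.reduced
        Xc = X - X.mean(axis=0)
        Xc = Xc - Xc.mean(axis=1, keepdims=True)
        assert np.allclose(recon, Xc, atol=1e-8)

    def test_leading_axis_matches_eigendecomposition(self, rng):
        # 2-feature correlated Gaussian: whitening axis vs direct eigenvector
        cov = np.array([[2.0, 1.2], [1.2, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=5000).T  # 2 obs × 5000
        Xw = pca_reduce(X, 1, center="rows")
        axis = Xw.dewhitening[:, 0]
        axis /= np.linalg.norm(axis)
        Xc = X - X.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        lead = evecs[:, np.argmax(evals)]
        angle = np.degrees(np.arccos(np.clip(abs(axis @ lead), 0, 1)))
        assert angle < 1.0

    def test_whitened_rows_uncorrelated_unit_variance(self, rng):
        X = rng.standard_normal((30, 500))
        Xw = pca_reduce(X, 8)
        R = Xw.reduced @ Xw.reduced.T / Xw.reduced.shape[1]
        assert np.allclose(R, np.eye(8), atol=1e-6)

    def test_explained_variance_bookkeeping(self, rng):
        Xw = pca_reduce(rng.standard_normal((20, 300)), 5)
        assert Xw.explained_variance.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(Xw.explained_variance) <= 1e-12)

    def test_reconstruction_error_equals_discarded_eigenvalue_mass(self, rng):
        X = rng.standard_normal((25, 400))
        Xw = pca_reduce(X, 6)
        Xc = X - X.mean(axis=0)
        Xc = Xc - Xc.mean(axis=1, keepdims=True)
        resid = Xc - Xw.dewhitening @ Xw.reduced
        evals = np.sort(np.linalg.eigvalsh(Xc @ Xc.T))[::-1]
        assert np.sum(resid**2) == pytest.approx(evals[6:].sum(), abs=1e-8)

    def test_k_beyond_rank_rejected(self, rng):
        X = rng.standard_normal((10, 2)) @ rng.standard_normal((2, 50))
        with pytest.raises(ValueError, match="rank|exceeds"):
            pca_reduce(X, 5)


class TestInfomax:
    def test_recovers_laplace_sources(self, rng):
        S = rng.laplace(size=(2, 10000))
        A = rng.standard_normal((2, 2))
        Xw = pca_reduce(A @ S, 2, center="rows")
        _, Sest, _ = infomax_ica(Xw, seed=1)
        matched = best_match_r(S, Sest)
        assert np.all(matched >= 0.99)

    def test_gaussian_input_does_not_crash(self, rng):
        Xw = pca_reduce(rng.standard_normal((2, 2000)), 2, center="rows")
        W, S, conv = infomax_ica(Xw, seed=0, max_steps=64)
        assert np.isfinite(W).all() and np.isfinite(S).all()

    def test_same_seed_bitwise_identical(self, rng):
        S = rng.laplace(size=(3, 3000))
        Xw = pca_reduce(rng.standard_normal((3, 3)) @ S, 3, center="rows")
        W1, _, _ = infomax_ica(Xw, seed=11)
        W2, _, _ = infomax_ica(Xw, seed=11)
        assert np.array_equal(W1, W2)


class TestDecomposeStructural:
    def test_noiseless_exact_recovery_at_matched_order(self, atlas_small):
        stack, _ = simulate_structural_cohort(
            atlas_small, n_pd=20, n_hc=20, noise_sigma=0.0, seed=5)
        cfg = PipelineConfig(n_components=6, n_icasso_runs=3, seed=5)
        cs, _ = decompose_structural(stack, cfg, brain_mask=atlas_small.brain_mask)
        matched = best_match_r(atlas_small.flat_sources(), cs.maps)
        assert np.all(matched >= 0.99)

    def test_component_maps_are_zscored(self, small_bundle):
        maps = small_bundle.structural_all.maps
        assert np.allclose(maps.mean(axis=1), 0.0, atol=1e-8)
        assert np.allclose(maps.std(axis=1), 1.0, atol=1e-8)

    def test_planted_sources_recovered_with_noise(self, small_bundle):
        atlas = small_bundle.atlas
        matched = best_match_r(atlas.flat_sources(), small_bundle.structural_all.maps)
        assert (matched >= 0.9).sum() >= atlas.k_true - 1

    def test_too_few_subjects_rejected(self, atlas_small):
        stack, _ = simulate_structural_cohort(atlas_small, 10, 10, seed=1)
        cfg = PipelineConfig(n_components=25, n_icasso_runs=2, seed=0)
        with pytest.raises(ValueError, match="subjects"):
            decompose_structural(stack, cfg, brain_mask=atlas_small.brain_mask)


@pytest.fixture(scope="module")
def func_series(atlas_small):
    from covnet.cohort import simulate_functional_cohort

    series, _ = simulate_functional_cohort(
        atlas_small, n_subjects=8, n_volumes=100, rho_func=0.3,
        noise_sigma=0.5, seed=13)
    return [s.reshape(100, -1)[10:] for s in series]


class TestDecomposeFunctional:
    def test_recovers_cingulate_networks(self, atlas_small, func_series):
        cfg = PipelineConfig(n_components=6, n_icasso_runs=3, seed=2)
        cs, _ = decompose_functional(func_series, cfg,
                                     analysis_mask=np.ones(atlas_small.grid_shape, bool),
                                     brain_mask=atlas_small.brain_mask)
        F = atlas_small.flat_sources()
        ia = atlas_small.role_index("anterior_cingulate")
        ip = atlas_small.role_index("posterior_cingulate")
        matched = best_match_r(F[[ia, ip]], cs.maps)
        assert np.all(matched >= 0.8)

    def test_subject_order_permutation_invariant_up_to_sign(self, atlas_small,
                                                           func_series):
        cfg = PipelineConfig(n_components=6, n_icasso_runs=3, seed=2)
        mask = np.ones(atlas_small.grid_shape, bool)
        cs1, _ = decompose_functional(func_series, cfg, analysis_mask=mask)
        cs2, _ = decompose_functional(func_series[::-1], cfg, analysis_mask=mask)
        matched = best_match_r(cs1.maps, cs2.maps)
        assert np.all(matched >= 0.95)

    def test_single_subject_reduces_to_spatial_ica(self, atlas_small, func_series):
        cfg = PipelineConfig(n_components=4, n_icasso_runs=2, seed=3)
        mask = np.ones(atlas_small.grid_shape, bool)
        cs, _ = decompose_functional(func_series[:1], cfg, analysis_mask=mask)
        assert cs.maps.shape == (4, mask.sum())

    def test_inconsistent_voxel_counts_rejected(self, func_series):
        cfg = PipelineConfig(n_components=4, n_icasso_runs=2, seed=3)
        bad = [func_series[0], func_series[1][:, :-5]]
        with pytest.raises(ValueError, match="voxel"):
            decompose_functional(bad, cfg, analysis_mask=None)


class TestDualRegression:
    def test_exact_linear_model_recovery(self, rng):
        maps = rng.standard_normal((4, 600))
        tc = rng.standard_normal((50, 4))
        series = tc @ maps
        tcs, _ = dual_regression(series, maps)
        assert np.allclose(tcs, tc, atol=1e-6)

    def test_orthonormal_maps_equal_inner_products(self, rng):
        raw = rng.standard_normal((3, 400))
        raw -= raw.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(raw.T)
        maps = q.T  # orthonormal, zero-mean rows
        series = rng.standard_normal((30, 400))
        tcs, _ = dual_regression(series, maps)
        # normal equations for orthonormal zero-mean regressors = projections
        centered = series - series.mean(axis=1, keepdims=True)
        expected = centered @ maps.T
        assert np.allclose(tcs, expected, atol=1e-8)

    def test_constant_offset_absorbed_by_intercept(self, rng):
        maps = rng.standard_normal((3, 300))
        series = rng.standard_normal((40, 300))
        tcs1, _ = dual_regression(series, maps)
        tcs2, _ = dual_regression(series + 7.5, maps)
        assert np.allclose(tcs1, tcs2, atol=1e-9)

    def test_rank_deficient_maps_rejected(self, rng):
        m = rng.standard_normal((1, 200))
        maps = np.vstack([m, 2 * m, rng.standard_normal((1, 200))])
        with pytest.raises(ValueError, match="rank"):
            dual_regression(rng.standard_normal((20, 200)), maps)


class TestThresholdAndLabels:
    def test_threshold_basics(self, rng):
        assert threshold_map(np.zeros(100), 3.0).sum() == 0
        z = rng.standard_normal(100_000)
        frac = threshold_map(z, 3.0).mean()
        assert frac == pytest.approx(0.00135, abs=0.0005)
        assert threshold_map(z, 0.0).mean() == pytest.approx(0.5, abs=0.02)

    def test_planted_artifact_and_signal_labelled(self, small_bundle):
        atlas = small_bundle.atlas
        cs = small_bundle.structural_all
        matched = small_bundle.matched_components["all"]
        i_art = matched["artifact"]["component"]
        i_ant = matched["anterior_cingulate"]["component"]
        assert cs.labels[i_art] == "artifact"
        assert cs.labels[i_ant] == "signal"

    def test_all_ones_mask_means_everything_is_signal(self, rng):
        maps = zscore_maps(rng.standard_normal((3, 4000)))
        mask = np.ones((10, 20, 20), dtype=bool)
        labels = flag_artifact_components(maps, mask, mask, z_threshold=3.0)
        assert all(lab == "signal" for lab in labels)
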