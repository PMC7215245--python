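import numpy as np
import pytest
from scipy import stats

from neurometab import voxel
from neurometab.cohort import PlantedClusterSpec, generate_voxel_stack


def _cube_stack(rng, n=20, shape=(10, 10, 10)):
    mask = np.ones(shape, bool)
    data = rng.normal(size=(n, mask.sum()))
    return voxel.VoxelStack(data=data, mask=mask, voxel_size=(3.0, 3.0, 3.0))


class TestSoftImpute:
    def test_fully_observed_zero_penalty_is_identity(self, rng):
        X = rng.normal(size=(8, 5))
        out, fit = voxel.soft_impute(X, 0.0)
        np.testing.assert_allclose(out, X, atol=1e-10)

    def test_huge_penalty_gives_column_means(self, rng):
        X = rng.normal(size=(10, 6))
        X[3, 2] = np.nan
        lam = np.linalg.svd(np.nan_to_num(X), compute_uv=False)[0] * 10
        out, fit = voxel.soft_impute(X, lam)
        assert fit.rank == 0
        assert out[3, 2] == pytest.approx(np.nanmean(X[:, 2]))

    def test_low_rank_recovery(self, rng):
        U = rng.normal(size=(60, 2))
        V = rng.normal(size=(2, 20))
        M = U @ V
        X = M.copy()
        hole = rng.random(M.shape) < 0.3
        X[hole] = np.nan
        out, _ = voxel.soft_impute(X, 0.01, tol=1e-10, max_iter=3000)
        rel = np.linalg.norm(out[hole] - M[hole]) / np.linalg.norm(M[hole])
        assert rel < 0.01

    def test_objective_monotone_nonincreasing(self, rng):
        X = rng.normal(size=(30, 12))
        X[rng.random(X.shape) < 0.2] = np.nan
        _, fit = voxel.soft_impute(X, 0.5, tol=1e-12, max_iter=200)
        assert np.all(np.diff(fit.objective_trace) <= 1e-9)

    def test_observed_entries_untouched(self, rng):
        X = rng.normal(size=(15, 8))
        X[rng.random(X.shape) < 0.25] = np.nan
        obs = np.isfinite(X)
        out, _ = voxel.soft_impute(X, 1.0)
        np.testing.assert_array_equal(out[obs], X[obs])

    def test_empty_column_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        X[:, 1] = np.nan
        with pytest.raises(ValueError):
            voxel.soft_impute(X, 0.1)


class TestChooseLambda:
    def test_low_rank_prefers_small_lambda(self, rng):
        U = rng.normal(size=(40, 2))
        X = U @ rng.normal(size=(2, 15))
        X[rng.random(X.shape) < 0.2] = np.nan
        lam_max = np.linalg.svd(
            np.nan_to_num(X - np.nanmean(X, axis=0)), compute_uv=False
        )[0]
        lam = voxel.choose_lambda(X, np.random.default_rng(0))
        assert lam < lam_max / 2

    def test_pure_noise_prefers_large_lambda(self, rng):
        X = rng.normal(size=(40, 15))
        X[rng.random(X.shape) < 0.2] = np.nan
        lam_max = np.linalg.svd(
            np.nan_to_num(X - np.nanmean(X, axis=0)), compute_uv=False
        )[0]
        lam = voxel.choose_lambda(X, np.random.default_rng(0), n_lambdas=8)
        assert lam > lam_max / 10  # upper half of the geometric path

    def test_deterministic_given_rng(self, rng):
        X = rng.normal(size=(20, 10))
        X[rng.random(X.shape) < 0.2] = np.nan
        a = voxel.choose_lambda(X, np.random.default_rng(5))
        b = voxel.choose_lambda(X, np.random.default_rng(5))
        assert a == b


class TestSpearmanMap:
    def test_perfect_monotone_relation(self, rng):
        stack = _cube_stack(rng, n=10)
        x = np.arange(10.0)
        stack.data[:] = np.sort(stack.data, axis=0)  # increasing in x at all voxels
        rho = voxel.spearman_map(x, stack)
        np.testing.assert_allclose(rho, 1.0)

    def test_hand_computed_rho(self):
        # x=[1,2,3,4], y=[2,1,4,3]: sum d^2 = 4, rho = 1 - 24/60 = 0.6
        mask = np.ones((1, 1, 1), bool)
        stack = voxel.VoxelStack(
            data=np.array([[2.0], [1.0], [4.0], [3.0]]), mask=mask,
            voxel_size=(3, 3, 3),
        )
        rho = voxel.spearman_map([1, 2, 3, 4], stack)
        assert rho[0] == pytest.approx(0.6)

    def test_matches_scipy_oracle(self, rng):
        stack = _cube_stack(rng, n=15, shape=(4, 4, 4))
        x = rng.normal(size=15)
        rho = voxel.spearman_map(x, stack)
        oracle = np.array([
            stats.spearmanr(x, stack.data[:, v]).statistic
            for v in range(stack.data.shape[1])
        ])
        np.testing.assert_allclose(rho, oracle, atol=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        stack = _cube_stack(rng, n=12, shape=(3, 3, 3))
        x = rng.normal(size=12)
        a = voxel.spearman_map(x, stack)
        b = voxel.spearman_map(np.exp(x), stack)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestPartialSpearman:
    def test_independent_covariate_leaves_correlation(self, rng):
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        c = rng.normal(size=500)
        full = stats.spearmanr(x, y).statistic
        assert voxel.partial_spearman(x, y, c) == pytest.approx(full, abs=0.05)

    def test_y_equal_to_covariate_vanishes(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        assert abs(voxel.partial_spearman(x, y, y)) < 1e-10

    def test_matches_residualization_oracle(self):
        x = np.array([3.0, 1, 4, 1.5, 5, 9])
        y = np.array([2.0, 7, 1, 8, 2, 8])
        c = np.array([1.0, 0, 1, 0, 1, 0])
        rx, ry, rc = (stats.rankdata(v) for v in (x, y, c))
        Z = np.column_stack([np.ones(6), rc])
        ex = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        ey = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        oracle = np.corrcoef(ex, ey)[0, 1]
        assert voxel.partial_spearman(x, y, c) == pytest.approx(oracle, abs=1e-12)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            voxel.partial_spearman(rng.normal(size=6), rng.normal(size=6),
                                   np.ones(6))


class TestBootstrapPMap:
    def test_perfect_relation_hits_floor(self, rng):
        stack = _cube_stack(rng, n=12, shape=(3, 3, 3))
        x = np.arange(12.0)
        stack.data[:] = np.sort(stack.data, axis=0)
        p = voxel.bootstrap_p_map(x, stack, B=100, rng=rng)
        np.testing.assert_allclose(p, 1 / 101)

    def test_null_p_roughly_uniform(self, rng):
        stack = _cube_stack(rng, n=40, shape=(8, 8, 8))
        x = rng.normal(size=40)
        p = voxel.bootstrap_p_map(x, stack, B=200, rng=rng)
        # discrete & floored, so compare coarse quantiles not exact KS
        assert np.mean(p < 0.5) == pytest.approx(0.5, abs=0.08)
        assert np.mean(p < 0.1) == pytest.approx(0.1, abs=0.05)

    def test_reproducible_under_seed(self, rng):
        stack = _cube_stack(rng, n=10, shape=(3, 3, 3))
        x = rng.normal(size=10)
        a = voxel.bootstrap_p_map(x, stack, 50, np.random.default_rng(1))
        b = voxel.bootstrap_p_map(x, stack, 50, np.random.default_rng(1))
        np.testing.assert_array_equal(a, b)


class TestEstimateFWHM:
    def test_round_trip(self, rng):
        mask = np.ones((20, 20, 20), bool)
        maps = np.stack([
            voxel.smooth_noise_field(mask.shape, 6.0, (3, 3, 3), rng)
            for _ in range(8)
        ])
        fw = voxel.estimate_fwhm(maps, mask, (3, 3, 3))
        assert np.all(np.abs(fw - 6.0) < 1.0)

    def test_unsmoothed_noise_below_voxel_sentinel(self, rng):
        mask = np.ones((16, 16, 16), bool)
        fw = voxel.estimate_fwhm(rng.standard_normal(mask.shape), mask, (3, 3, 3))
        assert np.all(fw < 3.0)

    def test_monotone_in_true_smoothness(self, rng):
        mask = np.ones((24, 24, 24), bool)
        ests = []
        for f in (3.0, 6.0, 9.0, 12.0):
            maps = np.stack([
                voxel.smooth_noise_field(mask.shape, f, (3, 3, 3), rng)
                for _ in range(4)
            ])
            ests.append(voxel.estimate_fwhm(maps, mask, (3, 3, 3)).mean())
        assert np.all(np.diff(ests) > 0)


class TestClusterSizeThreshold:
    def test_extreme_voxel_threshold_limit(self, rng):
        mask = np.ones((12, 12, 12), bool)
        thr = voxel.cluster_size_threshold(
            mask, 0.0, voxel_p=1.0 / mask.sum() / 100, n_sims=200, rng=rng
        )
        assert thr == 1

    def test_nondecreasing_in_smoothness(self):
        mask = np.ones((20, 20, 20), bool)
        thr = [
            voxel.cluster_size_threshold(
                mask, f, n_sims=300, rng=np.random.default_rng(1)
            )
            for f in (0.0, 6.0, 12.0)
        ]
        assert thr[0] <= thr[1] <= thr[2]

    def test_tiny_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            voxel.cluster_size_threshold(np.ones((2, 2, 2), bool), 6.0, rng=rng)


class TestExtractClusters:
    def _blob_stack(self):
        mask = np.ones((8, 8, 8), bool)
        stack = voxel.VoxelStack(
            data=np.zeros((4, mask.sum())), mask=mask, voxel_size=(3, 3, 3)
        )
        rho = np.zeros(mask.sum())
        p = np.ones(mask.sum())
        vol = np.zeros(mask.shape)
        vol[2, 2:4, 2:4] = 1  # 4 voxels
        vol[3, 2:4, 2:4] = 1  # + 4 voxels
        vol[4, 2:4, 2] = 1    # + 2 voxels -> 10 total, face-connected
        idx = vol[mask] > 0
        rho[idx] = 0.8
        p[idx] = 0.001
        return stack, rho, p, idx

    def test_single_blob_geometry(self):
        stack, rho, p, _ = self._blob_stack()
        out = voxel.extract_clusters(rho, p, stack, min_size=5)
        assert len(out) == 1
        assert out[0].n_voxels == 10
        assert out[0].size_mm3 == pytest.approx(270.0)
        assert out[0].peak_rho == pytest.approx(0.8)

    def test_min_size_filters_blob(self):
        stack, rho, p, _ = self._blob_stack()
        assert voxel.extract_clusters(rho, p, stack, min_size=11) == []

    def test_opposite_signs_never_merge(self):
        mask = np.ones((6, 6, 6), bool)
        stack = voxel.VoxelStack(
            data=np.zeros((4, mask.sum())), mask=mask, voxel_size=(3, 3, 3)
        )
        vol_r = np.zeros(mask.shape)
        vol_r[2, 2, 2] = 0.7   # positive voxel
        vol_r[2, 2, 3] = -0.7  # face-adjacent negative voxel
        rho = vol_r[mask]
        p = np.where(rho != 0, 0.001, 1.0)
        out = voxel.extract_clusters(rho, p, stack, min_size=1)
        assert len(out) == 2
        assert sorted(np.sign(c.peak_rho) for c in out) == [-1, 1]


class TestConnectivityGradient:
    def test_planted_negative_gradient_recovered(self):
        hits = []
        for s in range(10):
            r = np.random.default_rng(s)
            x = r.normal(size=50)
            shape = (12, 12, 12)
            ctl = voxel.smooth_noise_field(shape, 9.0, (3, 3, 3), r)
            # metabolite correlation strongest where control connectivity lowest
            rho_map = np.clip(-0.8 * (ctl - ctl.mean()) / ctl.std(), -0.9, 0.9)
            spec = PlantedClusterSpec(grid_shape=shape, clusters=[])
            stack = generate_voxel_stack(x, spec, r, rho_map=rho_map)
            rho, ci, p = voxel.connectivity_gradient(
                ctl[stack.mask], x, stack, B=100, rng=r
            )
            hits.append(rho)
        assert np.mean(np.array(hits) < 0) >= 0.9
        assert np.mean(hits) < -0.2

    def test_constant_control_map_rejected(self, rng):
        stack = _cube_stack(rng, n=10, shape=(3, 3, 3))
        with pytest.raises(ValueError):
            voxel.connectivity_gradient(np.ones(27), rng.normal(size=10),
                                        stack, B=10, rng=rng)


class TestRegionalSummary:
    def _clustered_stack(self, rng, x, n=60):
        spec = PlantedClusterSpec(grid_shape=(10, 10, 10),
                                  clusters=[((5, 5, 5), 3, 0.8)])
        stack = generate_voxel_stack(x, spec, rng)
        rho = voxel.spearman_map(x, stack)
        p = np.where(spec.cluster_mask()[stack.mask], 0.001, 1.0)
        clusters = voxel.extract_clusters(rho, p, stack, min_size=5)
        return stack, clusters

    def test_independent_hoc_changes_nothing(self, rng):
        x = rng.normal(size=60)
        stack, clusters = self._clustered_stack(rng, x)
        hoc = rng.integers(0, 2, size=60)
        out = voxel.regional_summary(x, stack, clusters, hoc, B=200, rng=rng)
        assert abs(out["change"]) < 0.05
        assert out["p_reduction"] > 0.05

    def test_hoc_mediated_correlation_collapses(self, rng):
        """Cluster signal driven by HOC itself: the metabolite-region
        correlation exists only through HOC, so partialling it out
        collapses the correlation."""
        hoc = np.repeat([0.0, 1.0], 30)
        driver = hoc + rng.normal(0, 0.05, size=60)   # what the voxels track
        x = hoc * 2.0 + rng.normal(0, 0.5, size=60)   # metabolite, own noise
        stack, clusters = self._clustered_stack(rng, driver)
        assert clusters, "fixture must produce a cluster"
        out = voxel.regional_summary(x, stack, clusters, hoc, B=200, rng=rng)
        assert abs(out["pcorr"]) < abs(out["corr"]) - 0.2
        assert out["change"] < -0.2

    def test_percent_reduction_formula(self, rng):
        x = rng.normal(size=60)
        stack, clusters = self._clustered_stack(rng, x)
        hoc = rng.integers(0, 2, size=60)
        out = voxel.regional_summary(x, stack, clusters, hoc, B=50, rng=rng)
        expected = 100.0 * (abs(out["pcorr"]) - abs(out["corr"])) / abs(out["corr"])
        assert out["percent_reduction"] == pytest.approx(expected)

    def test_empty_cluster_set(self, rng):
        stack = _cube_stack(rng, n=10, shape=(3, 3, 3))
        assert voxel.regional_summary(np.arange(10.0), stack, [], np.zeros(10)) == {}
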