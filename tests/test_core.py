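import numpy as np
import pytest
from hypothesis import given, strategies as st

import somkit as sk
from somkit.core import find_bmu, init_pca, init_random, missed_sample_probability

from conftest import two_cluster_data


class TestInitRandom:
    def test_reproducible_and_within_bounds(self, oils):
        grid = sk.GridSpec(8, 6)
        cb1 = init_random(grid, oils.data, seed=42)
        cb2 = init_random(grid, oils.data, seed=42)
        assert np.array_equal(cb1.W, cb2.W)
        assert (cb1.W >= oils.data.X.min(axis=0)).all()
        assert (cb1.W <= oils.data.X.max(axis=0)).all()
        assert not np.array_equal(cb1.W, init_random(grid, oils.data, seed=43).W)

    def test_uniform_moments(self):
        data = sk.Dataset(np.array([[0.0, -2.0], [4.0, 6.0]]))
        cb = init_random(sk.GridSpec(100, 100), data, seed=0)
        centre = np.array([2.0, 2.0])
        se = np.array([4.0, 8.0]) / np.sqrt(12) / 100  # uniform sd / sqrt(10,000)
        assert (np.abs(cb.W.mean(axis=0) - centre) < 3 * se).all()

    def test_constant_variable_stays_constant(self):
        data = sk.Dataset(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        cb = init_random(sk.GridSpec(4, 4), data, seed=0)
        assert (cb.W[:, 1] == 5.0).all()


class TestInitPCA:
    def test_codebook_lies_in_data_plane(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 7))
        coeffs = rng.standard_normal((40, 2)) * [3.0, 1.0]
        X = 1.5 + coeffs @ basis  # exact 2-D affine plane
        cb = init_pca(sk.GridSpec(6, 5), sk.Dataset(X))
        centred = cb.W - X.mean(axis=0)
        # residual after projecting onto the plane spanned by the basis
        proj = centred @ np.linalg.pinv(basis) @ basis
        assert np.allclose(centred, proj, atol=1e-9)

    def test_corner_cells_reconstruct_axes(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 5)) * [5.0, 2.0, 0.5, 0.2, 0.1]
        data = sk.Dataset(X)
        grid = sk.GridSpec(7, 6)
        cb = init_pca(grid, data)
        mean = X.mean(axis=0)
        _, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
        scale = s / np.sqrt(29)
        expected_corner = mean - scale[0] * Vt[0] - scale[1] * Vt[1]  # cell (0, 0) is (u, v) = (-1, -1)
        assert np.allclose(cb.W[0], expected_corner, atol=1e-9)
        expected_far = mean + scale[0] * Vt[0] + scale[1] * Vt[1]
        assert np.allclose(cb.W[grid.n_cells - 1], expected_far, atol=1e-9)

    def test_isotropic_data_has_equal_axis_scales(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((4000, 4))
        grid = sk.GridSpec(9, 9)
        cb = init_pca(grid, sk.Dataset(X))
        # corner-to-corner spans along the two map axes are 2*s1 and 2*s2
        row_span = np.linalg.norm(cb.W[grid.index(grid.n_rows - 1, 0)] - cb.W[0])
        col_span = np.linalg.norm(cb.W[grid.index(0, grid.n_cols - 1)] - cb.W[0])
        assert abs(row_span / col_span - 1) < 0.15

    def test_rank1_fallback_warns(self):
        X = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="rank"):
            cb = init_pca(sk.GridSpec(4, 4), sk.Dataset(X))
        assert np.isfinite(cb.W).all()


class TestFindBMU:
    def test_exact_row_and_tie_break(self):
        W = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [2.0, 0.0]])
        cb = sk.Codebook(W, sk.GridSpec(2, 2))
        assert find_bmu(cb, np.array([2.0, 0.0])) == 3
        assert find_bmu(cb, np.array([1.0, 1.0])) == 1  # tie j < k resolves to j

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        cb = sk.Codebook(rng.standard_normal((50, 8)), sk.GridSpec(10, 5))
        for _ in range(25):
            x = rng.standard_normal(8)
            oracle = int(np.argmin([np.linalg.norm(x - w) for w in cb.W]))
            assert find_bmu(cb, x) == oracle

    def test_rejects_non_finite(self):
        cb = sk.Codebook(np.zeros((4, 2)), sk.GridSpec(2, 2))
        with pytest.raises(ValueError):
            find_bmu(cb, np.array([np.nan, 0.0]))


class TestTrain:
    def test_vanishing_learning_rate_changes_nothing(self, oils, small_schedule):
        grid = sk.GridSpec(6, 5)
        sched = sk.TrainingSchedule(T=500, alpha0=1e-12, alphaT=1e-12, sigma0=2, sigmaT=0.5, seed=0)
        init = init_random(grid, oils.data, seed=0)
        out = sk.train(oils.data, grid=grid, schedule=sched, init=init)
        assert np.allclose(out.codebook.W, init.W, atol=1e-7)

    def test_single_cell_closed_form(self):
        """One cell, one sample, constant alpha: W_t = x + (1-a)^t (W_0 - x)."""
        x = np.array([2.0, -1.0, 0.5])
        data = sk.Dataset(x[None, :])
        grid = sk.GridSpec(1, 1)
        a, T = 0.3, 40
        sched = sk.TrainingSchedule(T=T, alpha0=a, alphaT=a, sigma0=1.0, sigmaT=1.0, seed=0)
        init = sk.Codebook(np.array([[10.0, 10.0, 10.0]]), grid, var_ids=data.var_ids)
        out = sk.train(data, grid=grid, schedule=sched, init=init)
        expected = x + (1 - a) ** T * (init.W[0] - x)
        assert np.allclose(out.codebook.W[0], expected, rtol=1e-10)

    def test_bitwise_determinism(self, oils, small_schedule):
        grid = sk.GridSpec(8, 6)
        r1 = sk.train(oils.data, grid=grid, schedule=small_schedule)
        r2 = sk.train(oils.data, grid=grid, schedule=small_schedule)
        assert np.array_equal(r1.codebook.W, r2.codebook.W)
        assert r1.log == r2.log

    @pytest.mark.parametrize("seed", range(20))
    def test_two_separable_clusters_partition_cleanly(self, seed):
        data, labels = two_cluster_data(seed)
        grid = sk.GridSpec(6, 5)
        sched = sk.TrainingSchedule(T=1200, sigma0=2.5, sigmaT=0.5, seed=seed)
        out = sk.train(data, grid=grid, schedule=sched)
        bmus = sk.assign_bmus(out.codebook, data)
        cells_a = set(bmus[labels == "a"])
        cells_b = set(bmus[labels == "b"])
        assert cells_a.isdisjoint(cells_b)

    def test_quantization_error_decreases_from_random_start(self, oils):
        grid = sk.GridSpec(8, 6)
        sched = sk.TrainingSchedule(T=2000, sigma0=3, seed=5)
        init = init_random(grid, oils.data, seed=5)
        before = sk.quantization_error(init, oils.data)
        out = sk.train(oils.data, grid=grid, schedule=sched, init=init)
        assert sk.quantization_error(out.codebook, oils.data) < before

    def test_rejects_bad_schedule(self):
        with pytest.raises(ValueError):
            sk.TrainingSchedule(T=0)
        with pytest.raises(ValueError):
            sk.TrainingSchedule(T=10, alpha0=0.1, alphaT=0.5)
        with pytest.raises(ValueError):
            sk.TrainingSchedule(T=10, sigma0=1.0, sigmaT=2.0)


class TestMissedSampleProbability:
    def test_reference_values(self):
        assert missed_sample_probability(100, 1000) == pytest.approx(4e-5, rel=0.1)
        assert missed_sample_probability(100, 10000) == pytest.approx(2e-44, rel=0.2)
        # exact value 0.13506...; the reference prints the truncated "0.13"
        assert missed_sample_probability(500, 1000) == pytest.approx(0.13, abs=0.006)
        assert missed_sample_probability(500, 1000) == pytest.approx((499 / 500) ** 1000)

    def test_edge_cases(self):
        assert missed_sample_probability(7, 0) == 1.0
        assert missed_sample_probability(1, 50) == 0.0
        with pytest.raises(ValueError):
            missed_sample_probability(0, 10)

    @given(st.integers(2, 10_000), st.integers(1, 700))
    def test_monotone_in_iterations_and_sample_count(self, N, T):
        p = missed_sample_probability(N, T)
        assert 0 <= p < 1
        assert p > missed_sample_probability(N, T + 1)
        assert p < missed_sample_probability(N + 1, T)


class TestQuantizationError:
    def test_zero_when_codebook_matches_data(self):
        X = np.random.default_rng(0).standard_normal((6, 3))
        cb = sk.Codebook(X, sk.GridSpec(3, 2))
        assert sk.quantization_error(cb, sk.Dataset(X)) == pytest.approx(0.0, abs=1e-12)

    def test_single_cell_equals_mean_distance_to_centroid(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 4))
        cb = sk.Codebook(X.mean(axis=0, keepdims=True), sk.GridSpec(1, 1))
        oracle = np.linalg.norm(X - X.mean(axis=0), axis=1).mean()
        assert sk.quantization_error(cb, sk.Dataset(X)) == pytest.approx(oracle, rel=1e-10)

    def test_adding_a_cell_never_increases(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((15, 3))
        W = rng.standard_normal((5, 3))
        small = sk.quantization_error(sk.Codebook(W, sk.GridSpec(5, 1)), sk.Dataset(X))
        W2 = np.vstack([W, rng.standard_normal(3)])
        big = sk.quantization_error(sk.Codebook(W2, sk.GridSpec(6, 1)), sk.Dataset(X))
        assert big <= small + 1e-12
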