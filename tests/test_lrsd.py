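import numpy as np
import pytest

from conftest import ista_reference

from cscrseg import (RunConfig, apg_decompose, build_patch_image,
                     decompose_block, reconstruct_from_patch_image,
                     singular_value_threshold, soft_threshold)


class TestPatchImage:
    def test_origin_count_100x100(self):
        pi = build_patch_image(np.zeros((100, 100)), 50, 10)
        assert len(pi.origins) == 36          # ((100-50)/10+1)^2
        assert pi.matrix.shape == (2500, 36)

    def test_single_patch_case(self):
        rng = np.random.default_rng(0)
        X = rng.random((50, 50))
        pi = build_patch_image(X, 50, 10)
        assert len(pi.origins) == 1
        np.testing.assert_array_equal(pi.matrix[:, 0], X.ravel())

    def test_boundary_clamped_origin(self):
        pi = build_patch_image(np.zeros((105, 50)), 50, 10)
        rows = sorted({r for r, _ in pi.origins})
        assert rows == [0, 10, 20, 30, 40, 50, 55]

    def test_too_small_block_rejected(self):
        with pytest.raises(ValueError):
            build_patch_image(np.zeros((40, 100)), 50, 10)

    @pytest.mark.parametrize("shape", [(50, 50), (100, 100), (105, 50),
                                       (73, 88), (64, 131)])
    def test_round_trip_bit_exact(self, shape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        X = rng.random(shape)
        pi = build_patch_image(X, 50, 10)
        # median of identical covering values is bit-exact; the mean incurs
        # one rounding per covering patch
        np.testing.assert_array_equal(
            reconstruct_from_patch_image(pi.matrix, pi, agg="median"), X)
        np.testing.assert_allclose(
            reconstruct_from_patch_image(pi.matrix, pi, agg="mean"), X,
            atol=1e-12)

    def test_median_robust_to_single_corrupted_patch(self):
        rng = np.random.default_rng(1)
        X = rng.random((100, 100))
        pi = build_patch_image(X, 50, 10)
        counts = np.zeros((100, 100), int)
        for r, c in pi.origins:
            counts[r:r + 50, c:c + 50] += 1
        # perturb one patch; pick a pixel covered by >= 3 patches
        px = tuple(np.argwhere(counts >= 3)[0])
        j = next(i for i, (r, c) in enumerate(pi.origins)
                 if r <= px[0] < r + 50 and c <= px[1] < c + 50)
        M = pi.matrix.copy()
        local = (px[0] - pi.origins[j][0]) * 50 + (px[1] - pi.origins[j][1])
        M[local, j] += 1.0
        rec = reconstruct_from_patch_image(M, pi, agg="median")
        assert rec[px] == X[px]


class TestProximalOperators:
    def test_soft_threshold_values(self):
        np.testing.assert_allclose(soft_threshold(np.array([3.0]), 1.0), 2.0)
        np.testing.assert_allclose(soft_threshold(np.array([-0.5]), 1.0), 0.0)
        x = np.array([-2.0, 0.3, 5.0])
        np.testing.assert_array_equal(soft_threshold(x, 0.0), x)
        with pytest.raises(ValueError):
            soft_threshold(x, -0.1)

    def test_svt_on_diagonal(self):
        X = np.diag([5.0, 2.0, 0.5])
        np.testing.assert_allclose(singular_value_threshold(X, 1.0),
                                   np.diag([4.0, 1.0, 0.0]), atol=1e-8)
        np.testing.assert_allclose(singular_value_threshold(X, 0.0), X,
                                   atol=1e-8)
        assert np.allclose(singular_value_threshold(X, 10.0), 0.0)


def _recovery_problem(seed=0, p=2500, q=36, frac=0.05):
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(p)
    u /= np.linalg.norm(u)
    v = rng.standard_normal(q)
    v /= np.linalg.norm(v)
    L0 = np.outer(u, v)
    S0 = np.zeros_like(L0)
    mask = rng.random(L0.shape) < frac
    S0[mask] = rng.choice([-1.0, 1.0], size=int(mask.sum()))
    return L0, S0


class TestAPG:
    def test_zero_matrix(self):
        res = apg_decompose(np.zeros((30, 10)))
        assert not res.L.any() and not res.S.any() and not res.N.any()
        assert res.converged

    def test_nan_rejected(self):
        bad = np.zeros((10, 10))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            apg_decompose(bad)

    def test_exact_recovery_rank1_plus_sparse(self):
        L0, S0 = _recovery_problem(seed=0)
        res = apg_decompose(L0 + S0)
        assert np.linalg.norm(res.L - L0) / np.linalg.norm(L0) <= 0.05
        assert np.linalg.norm(res.S - S0) / np.linalg.norm(S0) <= 0.05

    def test_objective_trace_non_increasing_after_burn_in(self):
        rng = np.random.default_rng(5)
        M = rng.random((60, 40))
        res = apg_decompose(M, max_iter=200)
        tr = res.objective_trace
        b = res.burn_in_iterations
        assert all(tr[i + 1] <= tr[i] + 1e-10 for i in range(b, len(tr) - 1))

    def test_consistency_L_plus_S_plus_N(self):
        rng = np.random.default_rng(6)
        M = rng.random((80, 30))
        res = apg_decompose(M)
        np.testing.assert_allclose(res.L + res.S + res.N, M, atol=1e-10)

    def test_agrees_with_unaccelerated_reference(self):
        # independent oracle: plain proximal gradient run to stagnation
        rng = np.random.default_rng(42)
        for _ in range(3):
            M = rng.standard_normal((20, 20))
            lam = 1.0 / np.sqrt(20)
            mu = 0.01 * np.linalg.norm(M, 2)
            res = apg_decompose(M, lambda_weight=lam, mu=mu, tol=1e-10,
                                max_iter=8000)
            L_ref, _ = ista_reference(M, lam, mu)
            rel = np.linalg.norm(res.L - L_ref) / np.linalg.norm(L_ref)
            assert rel <= 1e-3

    def test_sparsity_monotone_in_lambda(self):
        rng = np.random.default_rng(7)
        M = rng.random((40, 25))
        nnz = []
        for lam in (0.01, 0.05, 0.2, 1.0):
            res = apg_decompose(M, lambda_weight=lam, max_iter=200)
            nnz.append(int((np.abs(res.S) > 1e-12).sum()))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


class TestDecomposeBlock:
    def test_separable_background_recovered_as_low_rank(self):
        r = np.linspace(0, 1, 80)[:, None]
        c = np.linspace(0, 1, 90)[None, :]
        bg = 0.3 + 0.2 * np.exp(-(r - 0.4) ** 2) * np.exp(-(c - 0.6) ** 2)
        L_map, S_map, _ = decompose_block(bg, RunConfig())
        assert np.linalg.norm(L_map - bg) / np.linalg.norm(bg) <= 0.05

    def test_blob_argmax_near_true_center(self, small_phantom):
        from cscrseg import extract_roi, preprocess_fundus, \
            roi_covering_blobs, segment_and_inpaint
        pair, truth = small_phantom
        box = roi_covering_blobs(truth, pair.shape)
        I_a, fb = extract_roi(pair, box)
        G_P, _ = segment_and_inpaint(I_a, preprocess_fundus(fb))
        _, S_map, _ = decompose_block(G_P, RunConfig())
        am = np.unravel_index(np.argmax(S_map), S_map.shape)
        dists = [np.hypot(am[0] - (r - box.r0), am[1] - (c - box.c0))
                 for r, c in truth.blob_centers]
        assert min(dists) <= 3.0

    def test_sparse_map_non_negative(self):
        rng = np.random.default_rng(8)
        X = rng.random((60, 60))
        _, S_map, _ = decompose_block(X, RunConfig())
        assert S_map.min() >= 0.0
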