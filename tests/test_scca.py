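import dataclasses

import numpy as np
import pytest

from longscca.hypergraph import build_knn_hypergraph, laplacian
from longscca.scca import (
    PenaltyConfig,
    fit,
    fit_tgscca,
    objective,
    score_ccc,
    soft_threshold,
    update_u,
    update_V,
)


def _random_instance(rng, n=30, p=5, q=7, T=3, with_laplacians=False):
    lat = rng.normal(size=n)
    X = rng.normal(size=(n, q)) + np.outer(lat, rng.normal(size=q)) * 0.5
    Ys = [rng.normal(size=(n, p)) + np.outer(lat, rng.normal(size=p)) * 0.5 for _ in range(T)]
    if not with_laplacians:
        return X, Ys, None, None
    L1 = laplacian(build_knn_hypergraph(X, k=3))
    L2s = [laplacian(build_knn_hypergraph(y, k=3)) for y in Ys]
    return X, Ys, L1, L2s


class TestSoftThreshold:
    def test_hand_checkable_values(self):
        np.testing.assert_allclose(
            soft_threshold(np.array([2.0, -0.5, 0.1]), 0.5), [1.5, 0.0, 0.0]
        )

    def test_zero_penalty_is_identity(self, rng):
        z = rng.normal(size=10)
        np.testing.assert_allclose(soft_threshold(z, 0.0), z)

    def test_is_prox_of_l1(self, rng):
        # coordinate-wise: argmin 0.5 (x - z)^2 + lam |x| over a dense grid
        z = rng.normal(size=5) * 3
        lam = 0.7
        got = soft_threshold(z, lam)
        grid = np.linspace(-5, 5, 20001)
        for j in range(5):
            vals = 0.5 * (grid - z[j]) ** 2 + lam * np.abs(grid)
            assert abs(got[j] - grid[np.argmin(vals)]) < 1e-3


class TestObjective:
    def test_zero_weights_zero_objective(self, rng):
        X, Ys, _, _ = _random_instance(rng)
        cfg = PenaltyConfig(lam1=1, lam2=1, lamt=1)
        assert objective(np.zeros(7), np.zeros((5, 3)), X, Ys, None, None, cfg) == 0.0

    def test_penalty_free_single_time_reduction(self, rng):
        X, Ys, _, _ = _random_instance(rng, T=1)
        u = rng.normal(size=7)
        v = rng.normal(size=5)
        got = objective(u, v, X, Ys[:1], None, None, PenaltyConfig())
        assert got == pytest.approx(-(u @ X.T @ Ys[0] @ v), abs=1e-12)

    def test_matches_explicit_loop_recomputation(self, rng):
        X, Ys, L1, L2s = _random_instance(rng, with_laplacians=True)
        u = rng.normal(size=7)
        V = rng.normal(size=(5, 3))
        cfg = PenaltyConfig(lam1=0.3, lam2=0.2, lamt=0.1, beta1=0.4, beta2=0.5)
        expected = 0.0
        for t in range(3):
            xu = X @ u
            yv = Ys[t] @ V[:, t]
            expected -= sum(xu[i] * yv[i] for i in range(len(xu)))
            expected += cfg.beta2 * sum(
                yv[i] * L2s[t][i, j] * yv[j] for i in range(30) for j in range(30)
            )
        expected += cfg.lam1 * sum(abs(x) for x in u)
        expected += cfg.lam2 * sum(np.sqrt((V[j] ** 2).sum()) for j in range(5))
        expected += cfg.lamt * sum(
            np.sqrt(((V[:, t + 1] - V[:, t]) ** 2).sum()) for t in range(2)
        )
        xu = X @ u
        expected += cfg.beta1 * sum(
            xu[i] * L1[i, j] * xu[j] for i in range(30) for j in range(30)
        )
        got = objective(u, V, X, Ys, L1, L2s, cfg)
        assert got == pytest.approx(expected, abs=1e-9 * max(1, abs(expected)))

    def test_shape_mismatch_rejected(self, rng):
        X, Ys, _, _ = _random_instance(rng)
        with pytest.raises(ValueError):
            objective(np.zeros(6), np.zeros((5, 3)), X, Ys, None, None, PenaltyConfig())


class TestUpdateU:
    def test_lasso_null_condition_exact_zero(self, rng):
        X, Ys, _, _ = _random_instance(rng)
        V = rng.normal(size=(5, 3))
        c = sum(X.T @ (Ys[t] @ V[:, t]) for t in range(3))
        cfg = PenaltyConfig(lam1=np.abs(c).max() * 1.001)
        u = update_u(rng.normal(size=7), V, X, Ys, None, cfg)
        assert (u == 0).all()

    def test_diag_mode_returns_thresholded_cross_covariance(self, rng):
        # in the high-dimensional regime the quadratic-free update is
        # proportional to sum_t X^T Yt vt
        X, Ys, _, _ = _random_instance(rng)
        V = rng.normal(size=(5, 3))
        c = sum(X.T @ (Ys[t] @ V[:, t]) for t in range(3))
        cfg = PenaltyConfig(lam1=0.0, cov="diag")
        u = update_u(np.zeros(7), V, X, Ys, None, cfg)
        expect = c / np.diag(X.T @ X)
        expect = expect / np.linalg.norm(X @ expect)
        cos = abs(u @ expect) / (np.linalg.norm(u) * np.linalg.norm(expect))
        assert cos > 1 - 1e-10

    def test_block_optimality_vs_dense_grid(self, rng):
        # 2-feature toy: our feasible point is at least as good as the best
        # grid point of the constrained block problem
        n = 40
        X = rng.normal(size=(n, 2))
        Y = rng.normal(size=(n, 3))
        v = rng.normal(size=3)
        L1 = laplacian(build_knn_hypergraph(X, k=3))
        cfg = PenaltyConfig(lam1=0.3, beta1=0.5, cov="full")
        u = update_u(np.zeros(2), v, X, [Y], L1, cfg)
        c = X.T @ (Y @ v)
        M = X.T @ L1 @ X

        def block(uu):
            return -uu @ c + cfg.beta1 * uu @ M @ uu + cfg.lam1 * np.abs(uu).sum()

        grid = np.linspace(-2, 2, 401)
        best = np.inf
        for a in grid:
            uu = np.stack(np.broadcast_arrays(np.full_like(grid, a), grid), axis=1)
            feas = np.linalg.norm(uu @ X.T, axis=1) <= 1.0
            if feas.any():
                vals = (
                    -(uu @ c)
                    + cfg.beta1 * np.einsum("ij,jk,ik->i", uu, M, uu)
                    + cfg.lam1 * np.abs(uu).sum(axis=1)
                )
                best = min(best, vals[feas].min())
        assert np.linalg.norm(X @ u) <= 1 + 1e-8
        assert block(u) <= best + 1e-2


class TestUpdateV:
    def test_fusion_limit_equalizes_columns(self, rng):
        X, Ys, _, _ = _random_instance(rng)
        u = rng.normal(size=7)
        cfg = PenaltyConfig(lamt=1e6, inner_max_iter=500)
        V = update_V(u, rng.normal(size=(5, 3)), X, Ys, None, cfg)
        assert np.abs(V - V[:, [0]]).max() < 1e-4

    def test_group_lasso_null_condition(self, rng):
        X, Ys, _, _ = _random_instance(rng)
        u = rng.normal(size=7)
        xu = X @ u
        B = np.column_stack([Ys[t].T @ xu for t in range(3)])
        cfg = PenaltyConfig(lam2=np.linalg.norm(B, axis=1).max() * 1.001)
        V = update_V(u, rng.normal(size=(5, 3)), X, Ys, None, cfg)
        assert (V == 0).all()

    def test_block_optimality_vs_dense_grid(self, rng):
        # q=2, T=2 toy, value-level agreement with a 4-D grid oracle
        n = 25
        X = rng.normal(size=(n, 3))
        Ys = [rng.normal(size=(n, 2)) for _ in range(2)]
        u = rng.normal(size=3)
        cfg = PenaltyConfig(lam2=0.2, lamt=0.2, cov="full", inner_max_iter=500)
        V = update_V(u, np.zeros((2, 2)), X, Ys, None, cfg)
        xu = X @ u
        B = np.column_stack([Ys[t].T @ xu for t in range(2)])

        def block(W):
            val = 0.0
            for t in range(2):
                yv = Ys[t] @ W[:, t]
                if np.linalg.norm(yv) > 1 + 1e-9:
                    return np.inf
                val -= B[:, t] @ W[:, t]
            val += cfg.lam2 * np.linalg.norm(W, axis=1).sum()
            val += cfg.lamt * np.linalg.norm(W[:, 1] - W[:, 0])
            return val

        grid = np.linspace(-1, 1, 41)
        best = np.inf
        for a in grid:
            for b in grid:
                for cc in grid:
                    for d in grid:
                        best = min(best, block(np.array([[a, cc], [b, d]])))
        assert block(V) <= best + 5e-2


class TestFit:
    def test_matches_classical_cca_when_penalty_free(self, rng):
        import scipy.linalg as sla

        n, p, q = 50, 5, 4
        lat = rng.normal(size=n)
        X = rng.normal(size=(n, q))
        X[:, 0] += lat
        Y = rng.normal(size=(n, p))
        Y[:, 0] += lat
        model = fit(X, [Y], cfg=PenaltyConfig(tol=1e-10, max_iter=500))
        got = score_ccc(model, X, [Y])[0]
        Xc = (X - X.mean(0)) / X.std(0)
        Yc = (Y - Y.mean(0)) / Y.std(0)
        K = (
            sla.sqrtm(np.linalg.inv(Xc.T @ Xc))
            @ (Xc.T @ Yc)
            @ sla.sqrtm(np.linalg.inv(Yc.T @ Yc))
        )
        rho = np.linalg.svd(K, compute_uv=False)[0]
        assert abs(got - rho) < 1e-4

    def test_no_signal_with_moderate_penalty_returns_null(self, rng):
        n = 400
        X = rng.normal(size=(n, 6))
        Ys = [rng.normal(size=(n, 5)) for _ in range(2)]
        model = fit_tgscca(X, Ys, PenaltyConfig(lam1=0.9, lam2=0.01, cov="diag"))
        assert (model.u == 0).all()

    def test_objective_trace_monotone_on_random_instances(self, rng):
        for i in range(20):
            with_l = i % 2 == 0
            X, Ys, L1, L2s = _random_instance(rng, with_laplacians=with_l)
            cfg = PenaltyConfig(
                lam1=0.1, lam2=0.05, lamt=0.05,
                beta1=0.2 if with_l else 0.0, beta2=0.2 if with_l else 0.0,
            )
            model = fit(X, Ys, L1, L2s, cfg)
            diffs = np.diff(model.objective_trace)
            assert (diffs <= 1e-10).all()

    def test_scale_constraints_hold_at_return(self, rng):
        X, Ys, _, _ = _random_instance(rng)
        model = fit_tgscca(X, Ys, PenaltyConfig(lam1=0.05, lam2=0.05, lamt=0.05))
        Xs = (X - X.mean(0)) / (X.std(0) * np.sqrt(X.shape[0]))
        assert np.linalg.norm(Xs @ model.u) <= 1 + 1e-8
        for t, Y in enumerate(Ys):
            Yt = (Y - Y.mean(0)) / (Y.std(0) * np.sqrt(Y.shape[0]))
            assert np.linalg.norm(Yt @ model.V[:, t]) <= 1 + 1e-8

    def test_baseline_is_fit_with_zero_hypergraph_weights(self, rng):
        X, Ys, _, _ = _random_instance(rng)
        cfg = PenaltyConfig(lam1=0.1, lam2=0.05, lamt=0.05, beta1=0.7, beta2=0.7)
        a = fit_tgscca(X, Ys, cfg)
        b = fit(X, Ys, None, None, dataclasses.replace(cfg, beta1=0.0, beta2=0.0))
        np.testing.assert_array_equal(a.u, b.u)
        np.testing.assert_array_equal(a.V, b.V)

    def test_identical_time_points_reduce_to_single_time(self, rng):
        n, p, q = 60, 4, 5
        lat = rng.normal(size=n)
        X = rng.normal(size=(n, q)) + np.outer(lat, rng.normal(size=q))
        Y = rng.normal(size=(n, p)) + np.outer(lat, rng.normal(size=p))
        cfg = PenaltyConfig(tol=1e-12, max_iter=1000)
        m4 = fit(X, [Y, Y, Y, Y], cfg=cfg)
        m1 = fit(X, [Y], cfg=cfg)
        u4 = m4.u / np.linalg.norm(m4.u)
        u1 = m1.u / np.linalg.norm(m1.u)
        assert min(np.abs(u4 - u1).max(), np.abs(u4 + u1).max()) < 1e-6

    def test_hypergraph_penalty_reduces_projection_roughness(self, rng):
        X, Ys, L1, L2s = _random_instance(rng, n=40, with_laplacians=True)
        rough = []
        for beta in (0.0, 0.1, 10.0):
            cfg = PenaltyConfig(lam1=0.01, beta1=beta, cov="full")
            model = fit(X, Ys, L1, L2s, cfg)
            xu = _standardized(X) @ model.u
            nrm = np.linalg.norm(xu)
            rough.append((xu @ L1 @ xu) / nrm**2 if nrm > 0 else 0.0)
        assert rough[0] >= rough[1] - 1e-9
        assert rough[1] >= rough[2] - 1e-9

    def test_constant_feature_warns_and_gets_zero_weight(self, rng):
        X, Ys, _, _ = _random_instance(rng)
        X[:, 3] = 2.5
        with pytest.warns(UserWarning, match="constant"):
            model = fit_tgscca(X, Ys, PenaltyConfig(lam1=0.1))
        assert model.u[3] == 0


def _standardized(M):
    return (M - M.mean(0)) / (M.std(0) * np.sqrt(M.shape[0]))
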