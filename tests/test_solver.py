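"""Unit and property tests for the proximal-gradient solver layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netdiff import (
    CoeffPair,
    DesignPair,
    SolverConfig,
    center_columns,
    grad_g1,
    lambda1_max,
    lambda2_max,
    lasso_cd,
    prox_pair,
    soft_threshold,
    solve_joint,
    step_size,
)
from netdiff.solver import objective

from conftest import make_design


def brute_force_prox(t, t_tilde, lam1, lam2, half_width=6.0, grid=201, rounds=5):
    """Dense 2-D grid oracle with iterative zooming for the prox subproblem.

    The objective is convex but non-smooth along the kink manifolds
    (x = y, x = 0, y = 0); each round therefore evaluates a 2-D grid
    around the current best point PLUS 1-D grids lying exactly on those
    manifolds, then zooms in.  Five rounds bring the spacing below 1e-8.
    """

    def f(x, y):
        return (
            lam1 * (np.abs(x) + np.abs(y))
            + lam2 * np.abs(x - y)
            + 0.5 * ((x - t) ** 2 + (y - t_tilde) ** 2)
        )

    cx, cy, w = t, t_tilde, half_width
    for _ in range(rounds):
        xs = np.linspace(cx - w, cx + w, grid)
        ys = np.linspace(cy - w, cy + w, grid)
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        pts_x = [xx.ravel()]
        pts_y = [yy.ravel()]
        diag = np.linspace(0.5 * (cx + cy) - w, 0.5 * (cx + cy) + w, grid * 4)
        pts_x += [diag, xs, np.zeros_like(ys), np.array([0.0])]
        pts_y += [diag, np.zeros_like(xs), ys, np.array([0.0])]
        px = np.concatenate(pts_x)
        py = np.concatenate(pts_y)
        vals = f(px, py)
        k = int(np.argmin(vals))
        cx, cy = px[k], py[k]
        w = 3.0 * w / (grid - 1)
    return np.array([cx, cy])


class TestCentering:
    def test_mean_removal(self):
        centered, means = center_columns(np.array([[1.0], [3.0]]))
        assert np.allclose(centered.ravel(), [-1.0, 1.0])
        assert means[0] == 2.0

    def test_idempotent_on_centered_input(self):
        col = np.array([[-1.0], [0.0], [1.0]])
        centered, means = center_columns(col)
        assert np.array_equal(centered, col)
        assert means[0] == 0.0

    def test_column_sums_vanish(self, rng):
        centered, _ = center_columns(rng.normal(5.0, 2.0, (5, 3)))
        assert np.all(np.abs(centered.sum(axis=0)) <= 1e-10)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            center_columns(np.array([[1.0], [np.nan]]))

    def test_rejects_single_row(self):
        with pytest.raises(ValueError):
            center_columns(np.array([[1.0, 2.0]]))


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x,a,expected", [(2.0, 0.5, 1.5), (-2.0, 0.5, -1.5), (0.3, 0.5, 0.0)]
    )
    def test_branches(self, x, a, expected):
        assert soft_threshold(x, a) == pytest.approx(expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(-10, 10, allow_nan=False),
        st.floats(0, 5, allow_nan=False),
    )
    def test_matches_piecewise_definition(self, x, a):
        got = soft_threshold(x, a)
        if x > a:
            assert got == pytest.approx(x - a)
        elif x < -a:
            assert got == pytest.approx(x + a)
        else:
            assert got == 0.0


class TestProxPair:
    @pytest.mark.parametrize(
        "t,tt,l1,l2,expected",
        [
            (1.0, 0.5, 0.0, 0.3, (0.75, 0.75)),
            (2.0, 0.5, 0.2, 0.3, (1.5, 0.6)),
            (0.0, 0.0, 0.2, 0.3, (0.0, 0.0)),
            (-2.0, -0.5, 0.2, 0.3, (-1.5, -0.6)),
        ],
    )
    def test_frozen_examples(self, t, tt, l1, l2, expected):
        got = prox_pair(t, tt, l1, l2)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_numeric_oracle(self, rng):
        worst = 0.0
        for _ in range(200):
            t, tt = rng.normal(0, 2, 2)
            l1, l2 = rng.uniform(0, 1.5, 2)
            got = prox_pair(t, tt, l1, l2)
            exp = brute_force_prox(t, tt, l1, l2)
            worst = max(worst, abs(got[0] - exp[0]), abs(got[1] - exp[1]))
        assert worst <= 1e-6

    def test_vectorized_agrees_with_scalar(self, rng):
        t = rng.normal(size=6)
        tt = rng.normal(size=6)
        b, bt = prox_pair(t, tt, 0.3, 0.2)
        for j in range(6):
            sb, sbt = prox_pair(t[j], tt[j], 0.3, 0.2)
            assert b[j] == pytest.approx(sb)
            assert bt[j] == pytest.approx(sbt)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            prox_pair(1.0, 1.0, -0.1, 0.0)


class TestGradient:
    def test_zero_coefficients(self, rng):
        design, _, _ = make_design(rng)
        p = design.n_predictors
        g = grad_g1(CoeffPair(np.zeros(p), np.zeros(p)), design)
        expected = np.concatenate(
            [
                -2.0 * design.design_a.T @ design.response_a,
                -2.0 * design.design_b.T @ design.response_b,
            ]
        )
        assert np.allclose(g, expected)

    def test_least_squares_stationary_point(self, rng):
        # orthonormal columns: beta = Z^T y zeroes the gradient block
        q, _ = np.linalg.qr(rng.standard_normal((20, 5)))
        ya, yb = rng.standard_normal(20), rng.standard_normal(20)
        design = DesignPair(ya - ya.mean(), q - q.mean(0), yb - yb.mean(), q - q.mean(0))
        za, zb = design.design_a, design.design_b
        # re-orthonormalize after centering
        qa, _ = np.linalg.qr(za)
        qb, _ = np.linalg.qr(zb)
        design = DesignPair(design.response_a, qa, design.response_b, qb)
        coeffs = CoeffPair(qa.T @ design.response_a, qb.T @ design.response_b)
        assert np.allclose(grad_g1(coeffs, design), 0.0, atol=1e-10)

    def test_matches_finite_differences(self, rng):
        design, _, _ = make_design(rng, n=12, p=4)
        p = design.n_predictors
        coeffs = CoeffPair(rng.normal(size=p), rng.normal(size=p))
        g = grad_g1(coeffs, design)
        h = 1e-6
        stacked = coeffs.stacked
        for k in range(2 * p):
            up, dn = stacked.copy(), stacked.copy()
            up[k] += h
            dn[k] -= h
            f_up = objective(CoeffPair(up[:p], up[p:]), design, 0.0, 0.0)
            f_dn = objective(CoeffPair(dn[:p], dn[p:]), design, 0.0, 0.0)
            assert g[k] == pytest.approx((f_up - f_dn) / (2 * h), abs=1e-4)

    def test_dimension_mismatch(self, rng):
        design, _, _ = make_design(rng, p=4)
        with pytest.raises(ValueError):
            grad_g1(CoeffPair(np.zeros(3), np.zeros(3)), design)


class TestStepSize:
    def test_identity_designs(self):
        eye = np.eye(2)
        design = DesignPair(np.array([1.0, -1.0]), eye, np.array([1.0, -1.0]), eye)
        step, lip = step_size(design, "eigen")
        assert (step, lip) == (pytest.approx(0.25), pytest.approx(4.0))
        step, lip = step_size(design, "trace")
        assert (step, lip) == (pytest.approx(0.125), pytest.approx(8.0))

    def test_eigen_matches_dense_decomposition(self, rng):
        design, _, _ = make_design(rng, n=6, p=3)
        _, lip = step_size(design, "eigen")
        ga = np.linalg.eigvalsh(design.design_a.T @ design.design_a)[-1]
        gb = np.linalg.eigvalsh(design.design_b.T @ design.design_b)[-1]
        assert lip == pytest.approx(2.0 * (ga + gb), abs=1e-8)

    def test_trace_step_never_larger(self, rng):
        for _ in range(5):
            design, _, _ = make_design(rng)
            assert step_size(design, "trace")[0] <= step_size(design, "eigen")[0]

    def test_all_zero_designs_rejected(self):
        z = np.zeros((4, 2))
        design = DesignPair(np.zeros(4), z, np.zeros(4), z)
        with pytest.raises(ValueError):
            step_size(design)


class TestSolveJoint:
    def test_zero_solution_at_lambda1_max(self, rng):
        design, _, _ = make_design(rng)
        l1max = lambda1_max(design)
        res = solve_joint(design, SolverConfig(lam1=l1max, lam2=0.0))
        assert np.all(res.coeffs.stacked == 0.0)
        assert res.converged

    def test_lambda2_zero_matches_independent_lasso(self, rng):
        for _ in range(5):
            design, _, _ = make_design(rng)
            lam1 = 0.1 * lambda1_max(design)
            res = solve_joint(
                design, SolverConfig(lam1=lam1, lam2=0.0, tol=1e-12, max_iter=100_000)
            )
            ba = lasso_cd(design.response_a, design.design_a, lam1)
            bb = lasso_cd(design.response_b, design.design_b, lam1)
            gap = objective(res.coeffs, design, lam1, 0.0) - objective(
                CoeffPair(ba, bb), design, lam1, 0.0
            )
            assert abs(gap) <= 1e-8

    def test_fusion_at_lambda2_max(self, rng):
        for _ in range(5):
            design, _, _ = make_design(rng)
            lam1 = 0.2 * lambda1_max(design)
            lam2 = lambda2_max(design, lam1)
            res = solve_joint(
                design, SolverConfig(lam1=lam1, lam2=lam2, tol=1e-10, max_iter=100_000)
            )
            assert np.max(np.abs(res.coeffs.delta)) <= 1e-6

    def test_objective_path_non_increasing(self, rng):
        design, _, _ = make_design(rng)
        res = solve_joint(design, SolverConfig(lam1=1.0, lam2=0.5))
        assert np.all(np.diff(res.objective_path) <= 1e-9)

    def test_different_inits_reach_same_objective(self, rng):
        design, _, _ = make_design(rng)
        p = design.n_predictors
        cfg = SolverConfig(lam1=0.5, lam2=0.3, tol=1e-11, max_iter=100_000)
        r1 = solve_joint(design, cfg)
        r2 = solve_joint(design, cfg, init=CoeffPair(rng.normal(size=p), rng.normal(size=p)))
        f1 = objective(r1.coeffs, design, cfg.lam1, cfg.lam2)
        f2 = objective(r2.coeffs, design, cfg.lam1, cfg.lam2)
        assert abs(f1 - f2) <= 1e-7

    def test_non_convergence_warns_not_raises(self, rng):
        design, _, _ = make_design(rng)
        with pytest.warns(RuntimeWarning):
            res = solve_joint(design, SolverConfig(lam1=0.01, lam2=0.0, tol=1e-14, max_iter=2))
        assert not res.converged


class TestLassoCD:
    def test_orthonormal_closed_form(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((30, 5)))
        y = rng.standard_normal(30)
        lam = 0.4
        b = lasso_cd(y, q, lam)
        expected = np.array([soft_threshold(q[:, j] @ y, lam / 2) for j in range(5)])
        assert np.allclose(b, expected, atol=1e-9)

    def test_lambda_max_zeroes_solution(self, rng):
        z = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        lam = 2.0 * np.abs(z.T @ y).max()
        assert np.all(lasso_cd(y, z, lam) == 0.0)

    def test_unpenalized_limit_is_ols(self, rng):
        z = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        b = lasso_cd(y, z, 0.0)
        ols = np.linalg.lstsq(z, y, rcond=None)[0]
        assert np.allclose(b, ols, atol=1e-7)

    def test_kkt_residual_small(self, rng):
        z = rng.standard_normal((25, 10))
        y = z[:, 0] * 1.2 + 0.1 * rng.standard_normal(25)
        lam = 0.3 * 2.0 * np.abs(z.T @ y).max()
        b = lasso_cd(y, z, lam)
        g = 2.0 * (z.T @ (z @ b) - z.T @ y)
        nz = b != 0
        assert np.all(np.abs(g[nz] + lam * np.sign(b[nz])) <= 1e-8)
        assert np.all(np.abs(g[~nz]) <= lam + 1e-8)

    def test_agrees_with_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        z = rng.standard_normal((40, 8))
        y = z[:, :2] @ np.array([1.0, -0.7]) + 0.05 * rng.standard_normal(40)
        lam = 0.2 * 2.0 * np.abs(z.T @ y).max()
        b = lasso_cd(y, z, lam)
        # sklearn objective: (1/2n)||y-Zb||^2 + alpha ||b||_1  =>  alpha = lam/(2n)
        model = sklearn.Lasso(alpha=lam / (2 * 40), fit_intercept=False, tol=1e-12, max_iter=100000)
        model.fit(z, y)
        assert np.allclose(b, model.coef_, atol=1e-6)
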