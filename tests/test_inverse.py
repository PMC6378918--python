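"""Tikhonov solver equivalence with SVD/GSVD oracles, L-curve behaviour and
the Model/Results front door."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgikit.geometry import icosphere
from ecgikit.inverse import (
    EpicardialMapModel,
    RegularizationConfig,
    TikhonovSolver,
    find_corner_lambda,
    lcurve_point,
    reconstruct,
    regularizer,
    tikhonov_solve,
)
from ecgikit.sources import PotentialField


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def svd_filter_solution(A, b, lam):
    """Filter-factor solution for L = I: x = sum_i s_i/(s_i^2+lam^2) u_i'b v_i."""
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    f = s / (s**2 + lam**2)
    return Vt.T @ (f[:, None] * (U.T @ b))


def gsvd_filter_solution(A, L, b, lam):
    """Generalised filter solution via the QR + SVD route.

    Stack Z = [A; L] = QR, SVD Q1 = U C W'; then
    x = R^{-1} W diag(c_i / (c_i^2 + lam^2 (1 - c_i^2))) U'b,
    which is the GSVD filter-factor solution of min ||Ax-b||^2 + lam^2||Lx||^2.
    """
    m = A.shape[0]
    Z = np.vstack([A, L])
    Q, R = np.linalg.qr(Z)
    U, c, Wt = np.linalg.svd(Q[:m], full_matrices=False)
    f = c / (c**2 + lam**2 * (1.0 - c**2))
    return np.linalg.solve(R, Wt.T @ (f[:, None] * (U.T @ b)))


def first_difference(n):
    D = np.zeros((n - 1, n))
    for i in range(n - 1):
        D[i, i], D[i, i + 1] = -1.0, 1.0
    return D


def gaussian_kernel_problem(n=64, noise=0.01, seed=0, width=0.013):
    """Discrete smoothing-kernel test problem with a smooth truth signal.

    The kernel width (~0.8 grid spacings) keeps the smallest singular value
    near the 1% noise floor, so the L-curve has a single well-defined corner;
    for much wider kernels the spectrum decays far below the noise and the
    corner famously under-regularises.
    """
    t = np.linspace(0.0, 1.0, n)
    h = t[1] - t[0]
    A = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2 * width**2)) * h
    x_true = np.sin(2 * np.pi * t) + 0.5 * np.exp(-((t - 0.3) ** 2) / 0.01)
    b_clean = A @ x_true
    rng = np.random.default_rng(seed)
    b = b_clean + noise * np.linalg.norm(b_clean) / np.sqrt(n) * rng.normal(size=n)
    return A, x_true, b


def dense_grid_corner(A, b, L, lams):
    """Maximum-Menger-curvature lambda over a dense log-spaced grid."""
    pts = []
    for lam in lams:
        x = tikhonov_solve(A, b[:, None], L, lam)
        pts.append((np.log10(np.linalg.norm(A @ x - b[:, None])),
                    np.log10(np.linalg.norm(L @ x))))
    curv = []
    for i in range(1, len(lams) - 1):
        (x1, y1), (x2, y2), (x3, y3) = pts[i - 1], pts[i], pts[i + 1]
        cross = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
        d = (np.hypot(x2 - x1, y2 - y1) * np.hypot(x3 - x2, y3 - y2)
             * np.hypot(x3 - x1, y3 - y1))
        curv.append(2 * cross / d if d > 0 else 0.0)
    return lams[1:-1][int(np.argmax(curv))]


# ---------------------------------------------------------------------------
# Regulariser
# ---------------------------------------------------------------------------


class TestRegularizer:
    def test_order_zero_is_identity(self):
        heart = icosphere(1.0, 1)
        L = regularizer(0, heart)
        x = np.random.default_rng(0).normal(size=heart.n_vertices)
        np.testing.assert_allclose(L @ x, x)

    @pytest.mark.parametrize("order", [1, 2])
    def test_constants_annihilated(self, order):
        heart = icosphere(1.0, 1)
        L = regularizer(order, heart)
        c = np.full(heart.n_vertices, 4.2)
        np.testing.assert_allclose(L @ c, 0.0, atol=1e-10)

    def test_unsupported_order_rejected(self):
        heart = icosphere(1.0, 0)
        with pytest.raises(ValueError):
            regularizer(3, heart)


# ---------------------------------------------------------------------------
# Solver correctness
# ---------------------------------------------------------------------------


class TestTikhonovSolve:
    def test_unregularised_limit_square_system(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(6, 6)) + 6 * np.eye(6)
        K = rng.normal(size=(6, 2))
        X = tikhonov_solve(A, K, np.eye(6), 0.0)
        np.testing.assert_allclose(X, np.linalg.solve(A, K), atol=1e-10)

    def test_singular_at_lambda_zero_raises(self):
        A = np.zeros((4, 3))
        with pytest.raises(np.linalg.LinAlgError):
            tikhonov_solve(A, np.zeros((4, 1)), np.eye(3), 0.0)

    def test_oversmoothing_limit(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10, 6))
        K = rng.normal(size=(10, 1))
        smax = np.linalg.svd(A, compute_uv=False)[0]
        x0 = tikhonov_solve(A, K, np.eye(6), 1e-8)
        x_heavy = tikhonov_solve(A, K, np.eye(6), 1e6 * smax)
        assert np.linalg.norm(x_heavy) < 1e-4 * np.linalg.norm(x0)

    def test_matches_svd_filter_oracle(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(8, 6))
        b = rng.normal(size=(6 + 2, 1))[:8]
        x = tikhonov_solve(A, b, np.eye(6), 0.1)
        np.testing.assert_allclose(x, svd_filter_solution(A, b, 0.1), atol=1e-8)

    @given(st.integers(min_value=0, max_value=49))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_svd_and_gsvd_oracles_on_random_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        m = int(rng.integers(4, 31))
        n = int(rng.integers(3, min(m, 20) + 1))
        A = rng.normal(size=(m, n))
        b = rng.normal(size=(m, 1))
        lam = float(10 ** rng.uniform(-3, 1))
        x = tikhonov_solve(A, b, np.eye(n), lam)
        np.testing.assert_allclose(x, svd_filter_solution(A, b, lam), atol=1e-8)
        D = first_difference(n)
        xd = tikhonov_solve(A, b, D, lam)
        np.testing.assert_allclose(xd, gsvd_filter_solution(A, D, b, lam), atol=1e-6)

    def test_matches_gradient_descent_on_objective(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(4)
        A = rng.normal(size=(7, 5))
        b = rng.normal(size=(7, 1))
        L = first_difference(5)
        lam = 0.3

        def objective(x):
            return (np.linalg.norm(A @ x[:, None] - b) ** 2
                    + lam**2 * np.linalg.norm(L @ x[:, None]) ** 2)

        res = minimize(objective, np.zeros(5), method="BFGS", tol=1e-14)
        x = tikhonov_solve(A, b, L, lam)
        np.testing.assert_allclose(x[:, 0], res.x, atol=1e-5)


class TestStandardFormSolver:
    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_equivalent_to_direct_solver(self, order):
        heart = icosphere(1.0, 1)  # 42 nodes
        rng = np.random.default_rng(5)
        A = rng.normal(size=(60, heart.n_vertices))
        K = rng.normal(size=(60, 3))
        L = regularizer(order, heart)
        solver = TikhonovSolver(A, L)
        proj = solver.project(K)
        for lam in (1e-2, 0.5, 5.0):
            fast = solver.solve(proj, lam)
            direct = tikhonov_solve(A, K, L, lam)
            np.testing.assert_allclose(fast, direct, atol=1e-7)
            res, semi = solver.norms(proj, lam)
            assert res == pytest.approx(np.linalg.norm(A @ direct - K), rel=1e-6)
            Ld = L.toarray() if hasattr(L, "toarray") else L
            assert semi == pytest.approx(np.linalg.norm(Ld @ direct), rel=1e-6, abs=1e-9)


# ---------------------------------------------------------------------------
# L-curve
# ---------------------------------------------------------------------------


class TestLCurve:
    def test_monotonicity_in_lambda(self):
        A, _, b = gaussian_kernel_problem()
        L = np.eye(A.shape[1])
        lams = np.logspace(-6, 1, 12)
        pts = [lcurve_point(A, b[:, None], L, lam) for lam in lams]
        residuals = [p[0] for p in pts]
        seminorms = [p[1] for p in pts]
        assert np.all(np.diff(residuals) >= -1e-9)
        assert np.all(np.diff(seminorms) <= 1e-9)

    def test_residual_vanishes_for_consistent_square_system(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(5, 5)) + 5 * np.eye(5)
        b = A @ rng.normal(size=(5, 1))
        res, _ = lcurve_point(A, b, np.eye(5), 1e-10)
        assert res < 1e-6

    def test_corner_within_factor_three_of_dense_grid(self):
        A, x_true, b = gaussian_kernel_problem()
        L = np.eye(A.shape[1])
        lam = find_corner_lambda(A, b[:, None], L)
        solver = TikhonovSolver(A, L)
        lo, hi = solver.default_bracket()
        grid = np.logspace(np.log10(lo), np.log10(hi), 200)
        lam_grid = dense_grid_corner(A, b, L, grid)
        assert lam_grid / 3.0 <= lam <= lam_grid * 3.0

    def test_corner_reconstruction_error_near_optimal(self):
        A, x_true, b = gaussian_kernel_problem()
        L = np.eye(A.shape[1])
        lam = find_corner_lambda(A, b[:, None], L)
        x = tikhonov_solve(A, b[:, None], L, lam)[:, 0]
        err = np.linalg.norm(x - x_true)
        solver = TikhonovSolver(A, L)
        lo, hi = solver.default_bracket()
        errs = [
            np.linalg.norm(tikhonov_solve(A, b[:, None], L, l)[:, 0] - x_true)
            for l in np.logspace(np.log10(lo), np.log10(hi), 100)
        ]
        assert err <= 1.5 * min(errs)

    def test_bracket_shift_robustness(self):
        A, _, b = gaussian_kernel_problem()
        L = np.eye(A.shape[1])
        lam_a = find_corner_lambda(A, b[:, None], L)
        solver = TikhonovSolver(A, L)
        lo, hi = solver.default_bracket()
        cfg = RegularizationConfig(search=(0.5 * lo, 2.0 * hi, 50, 1e-3))
        lam_b = find_corner_lambda(A, b[:, None], L, cfg)
        assert lam_a / 2.1 <= lam_b <= lam_a * 2.1


# ---------------------------------------------------------------------------
# reconstruct and the Model/Results API
# ---------------------------------------------------------------------------


class TestReconstruct:
    def _problem(self):
        heart = icosphere(1.0, 1)
        rng = np.random.default_rng(7)
        A = rng.normal(size=(80, heart.n_vertices))
        truth = rng.normal(size=(heart.n_vertices, 4))
        K = PotentialField(A @ truth + 0.01 * rng.normal(size=(80, 4)), dt=2.0)
        return heart, A, K

    def test_single_timestep_modes_agree(self):
        heart, A, K = self._problem()
        K1 = PotentialField(K.values[:, :1])
        for mode in ("global", "per_timestep"):
            sol = reconstruct(A, K1, RegularizationConfig(order=0, lambda_mode=mode), heart=heart)
            assert np.isscalar(sol.lambda_used) or np.size(sol.lambda_used) == 1
        g = reconstruct(A, K1, RegularizationConfig(order=0, lambda_mode="global"), heart=heart)
        p = reconstruct(A, K1, RegularizationConfig(order=0, lambda_mode="per_timestep"), heart=heart)
        np.testing.assert_allclose(g.reconstructed.values, p.reconstructed.values, atol=1e-10)

    def test_global_mode_single_scalar_lambda(self):
        heart, A, K = self._problem()
        sol = reconstruct(A, K, RegularizationConfig(order=2), heart=heart)
        assert np.isscalar(sol.lambda_used)
        assert sol.reconstructed.values.shape == (heart.n_vertices, 4)
        assert sol.reconstructed.dt == 2.0
        assert len(sol.lcurve_trace) > 4

    def test_per_timestep_mode_lambda_per_column(self):
        heart, A, K = self._problem()
        sol = reconstruct(A, K, RegularizationConfig(order=1, lambda_mode="per_timestep"),
                          heart=heart)
        assert np.size(sol.lambda_used) == 4
        assert np.all(np.asarray(sol.lambda_used) > 0)


class TestModelResults:
    def _model(self):
        heart = icosphere(1.0, 1)
        rng = np.random.default_rng(8)
        A = rng.normal(size=(80, heart.n_vertices))
        truth = rng.normal(size=(heart.n_vertices, 3))
        K = PotentialField(A @ truth + 0.01 * rng.normal(size=(80, 3)))
        return EpicardialMapModel(A, K, heart, order=0), truth

    def test_fit_lcurve_and_summary(self):
        model, _ = self._model()
        res = model.fit()
        assert res.lambda_ > 0
        text = res.summary()
        assert "Tikhonov order" in text and "lambda" in text

    def test_fixed_lambda_matches_direct_solver(self):
        model, _ = self._model()
        res = model.fit(lam=0.2)
        direct = tikhonov_solve(model.transfer, model.bsp.values,
                                np.eye(model.heart.n_vertices), 0.2)
        np.testing.assert_allclose(res.reconstructed.values, direct, atol=1e-8)

    def test_rdms_diagnostic_near_zero_for_good_fit(self):
        model, truth = self._model()
        res = model.fit(lam=1e-4)
        summary = res.rdms(PotentialField(truth))
        assert summary.mean < 0.05

    def test_lcurve_plot_returns_axes(self):
        import matplotlib

        matplotlib.use("Agg")
        model, _ = self._model()
        ax = model.fit().plot_lcurve()
        assert ax.get_xlabel().startswith("residual")
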