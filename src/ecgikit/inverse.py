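"""Regularised inversion of body-surface potentials to epicardial potentials.

The inverse problem ``k_t = A r_t`` is ill-posed, so the solution is the
Tikhonov minimiser

    r_hat = argmin ||A r - k||^2 + lambda^2 ||L r||^2

with the regularisation order set by ``L``: identity (order 0), surface
gradient (order 1) or surface Laplacian (order 2).  The regularisation
parameter is selected at the corner of the L-curve (log residual norm vs log
solution seminorm), located by an iterative golden-section search on the
Menger curvature.  Either a single global lambda for the time-stacked system
or one lambda per timestep can be used.

Two solver routes exist deliberately: :func:`tikhonov_solve` factorises the
augmented least-squares system directly (stable, used for spot solves), while
:class:`TikhonovSolver` precomputes a standard-form SVD so that sweeping
lambda during the L-curve search costs almost nothing.  Both compute the same
minimiser.

A statsmodels-style front door is provided by :class:`EpicardialMapModel`,
whose :meth:`~EpicardialMapModel.fit` returns an
:class:`EpicardialMapResults` carrying the reconstruction, the selected
lambda, the L-curve trace and summary/diagnostic methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .geometry import TriangleMesh, cotangent_laplacian, gradient_operator
from .sources import PotentialField

_GOLDEN = (1.0 + sqrt(5.0)) / 2.0


@dataclass
class RegularizationConfig:
    """Choices controlling the Tikhonov inversion.

    ``search`` is ``(lambda_min, lambda_max, iterations, tolerance)``; the
    bounds may be ``None`` to derive the bracket from the singular spectrum
    of the (standard-form) design matrix.
    """

    order: int = 2
    lambda_mode: str = "global"
    search: tuple = (None, None, 50, 1e-3)

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError("order must be 0, 1 or 2")
        if self.lambda_mode not in ("global", "per_timestep"):
            raise ValueError("lambda_mode must be 'global' or 'per_timestep'")
        lo, hi, iters, tol = self.search
        if lo is not None and lo <= 0:
            raise ValueError("lambda_min must be positive")
        if lo is not None and hi is not None and not lo < hi:
            raise ValueError("need lambda_min < lambda_max")
        if iters < 4:
            raise ValueError("need at least 4 search iterations")
        if tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class InverseSolution:
    """Result of one inverse reconstruction."""

    reconstructed: PotentialField
    lambda_used: float | np.ndarray
    residual_norm: float | np.ndarray
    seminorm: float | np.ndarray
    lcurve_trace: list = field(default_factory=list)
    converged: bool = True
    order: int | None = None
    lambda_mode: str = "global"


def regularizer(order: int, heart: TriangleMesh):
    """The operator ``L`` for a given Tikhonov order on a heart mesh."""
    if order == 0:
        return sp.identity(heart.n_vertices, format="csr")
    if order == 1:
        return gradient_operator(heart)
    if order == 2:
        return cotangent_laplacian(heart)
    raise ValueError(f"unsupported Tikhonov order: {order}")


# ---------------------------------------------------------------------------
# Direct (augmented least-squares) solver
# ---------------------------------------------------------------------------


def _as_matrix(K) -> np.ndarray:
    if isinstance(K, PotentialField):
        return K.values
    return np.atleast_2d(np.asarray(K, dtype=float))


def tikhonov_solve(A, K, L, lam: float) -> np.ndarray:
    """Column-wise Tikhonov minimiser via an augmented QR factorisation.

    Solves ``min ||A R - K||^2 + lam^2 ||L R||^2`` without forming the
    normal equations.  ``lam = 0`` falls back to a plain (least-squares)
    solve and raises if the system is singular.
    """
    A = np.asarray(A.entries if hasattr(A, "entries") else A, dtype=float)
    K = _as_matrix(K)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0.0:
        m, n = A.shape
        rank = np.linalg.matrix_rank(A)
        if rank < n:
            raise np.linalg.LinAlgError(
                "singular system at lambda=0; use lambda > 0"
            )
        sol, *_ = np.linalg.lstsq(A, K, rcond=None)
        return sol
    Ld = L.toarray() if sp.issparse(L) else np.asarray(L, dtype=float)
    m, n = A.shape
    aug = np.vstack([A, lam * Ld])
    rhs = np.vstack([K, np.zeros((Ld.shape[0], K.shape[1]))])
    sol, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    return sol


def lcurve_point(A, K, L, lam: float) -> tuple[float, float]:
    """Residual norm and seminorm at one lambda (Frobenius over columns)."""
    if lam <= 0:
        raise ValueError("lambda must be positive for an L-curve point")
    A_ = np.asarray(A.entries if hasattr(A, "entries") else A, dtype=float)
    K_ = _as_matrix(K)
    X = tikhonov_solve(A_, K_, L, lam)
    residual = float(np.linalg.norm(A_ @ X - K_))
    seminorm = float(np.linalg.norm(L @ X))
    return residual, seminorm


# ---------------------------------------------------------------------------
# Standard-form SVD solver (fast lambda sweeps)
# ---------------------------------------------------------------------------


class TikhonovSolver:
    """Precomputed standard-form SVD for repeated solves with varying lambda.

    The penalty ``L`` (with an optional null space, e.g. constants for the
    gradient and Laplacian operators) is transformed away following Elden's
    oblique-pseudoinverse construction, after which every lambda costs only
    diagonal filter-factor arithmetic.  Produces the same minimiser as
    :func:`tikhonov_solve`.
    """

    def __init__(self, A, L):
        A = np.asarray(A.entries if hasattr(A, "entries") else A, dtype=float)
        P = (L.T @ L)
        P = P.toarray() if sp.issparse(P) else np.asarray(P, dtype=float)
        evals, U = sla.eigh(P)
        tol = max(evals.max(), 1.0) * 1e-12
        null = evals < tol
        self.k = int(null.sum())
        U1 = U[:, ~null]
        s = np.sqrt(evals[~null])
        Lpinv = U1 / s  # (n, r)
        if self.k > 0:
            W = U[:, null]  # (n, k)
            AW = A @ W
            Qw, Rw = np.linalg.qr(AW)
            AWpinv = sla.solve_triangular(Rw, Qw.T)  # (k, m)
            T = AWpinv @ (A @ Lpinv)
            self._L_A_pinv = Lpinv - W @ T
            self._W = W
            self._AWpinv = AWpinv
            self._Qw = Qw
            Abar = A @ self._L_A_pinv
        else:
            self._L_A_pinv = Lpinv
            self._W = None
            Abar = A @ Lpinv
        self._Ub, self.sigma, Vt = np.linalg.svd(Abar, full_matrices=False)
        self._Vb = Vt.T
        self.A = A

    def project(self, K) -> dict:
        """Precompute the K-dependent quantities shared by every lambda."""
        K = _as_matrix(K)
        if self._W is not None:
            Kp = K - self._Qw @ (self._Qw.T @ K)
            c = self._AWpinv @ K  # null-space coefficients, lambda-free
        else:
            Kp = K
            c = None
        beta = self._Ub.T @ Kp  # (r, T)
        perp2 = np.einsum("ij,ij->j", Kp, Kp) - np.einsum("ij,ij->j", beta, beta)
        return {"beta": beta, "perp2": np.maximum(perp2, 0.0), "c": c, "n_cols": K.shape[1]}

    def solve(self, proj: dict, lam: float) -> np.ndarray:
        f = self.sigma / (self.sigma**2 + lam**2)
        w = self._Vb @ (f[:, None] * proj["beta"])
        X = self._L_A_pinv @ w
        if self._W is not None:
            X = X + self._W @ proj["c"]
        return X

    def norms(self, proj: dict, lam: float, columns=None) -> tuple[float, float]:
        """(residual, seminorm) Frobenius norms at ``lam`` (optionally for a
        subset of timestep columns)."""
        beta = proj["beta"]
        perp2 = proj["perp2"]
        if columns is not None:
            beta = beta[:, columns]
            perp2 = perp2[columns]
        s2 = self.sigma**2
        res2 = ((lam**2 / (s2 + lam**2)) ** 2)[:, None] * beta**2
        semi2 = ((self.sigma / (s2 + lam**2)) ** 2)[:, None] * beta**2
        residual = float(np.sqrt(res2.sum() + perp2.sum()))
        seminorm = float(np.sqrt(semi2.sum()))
        return residual, seminorm

    def default_bracket(self) -> tuple[float, float]:
        smax = float(self.sigma.max())
        smin = float(self.sigma[self.sigma > 0].min()) if np.any(self.sigma > 0) else smax * 1e-12
        return max(smin, 1e-12 * smax), smax


# ---------------------------------------------------------------------------
# L-curve corner search
# ---------------------------------------------------------------------------


def _menger_curvature(p1, p2, p3) -> float:
    """Signed Menger curvature of three points in the (log rho, log eta) plane."""
    (x1, y1), (x2, y2), (x3, y3) = p1, p2, p3
    cross = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
    d12 = np.hypot(x2 - x1, y2 - y1)
    d23 = np.hypot(x3 - x2, y3 - y2)
    d13 = np.hypot(x3 - x1, y3 - y1)
    denom = d12 * d23 * d13
    if denom == 0.0:
        return 0.0
    return 2.0 * cross / denom


def _corner_search(point_fn, lam_lo, lam_hi, iterations, tolerance):
    """Iterative Menger-curvature corner location on the log-log L-curve.

    A coarse log-spaced curvature scan first brackets the corner (the flat
    left tail of ill-conditioned problems carries numerical wiggles that can
    trap a pure section search), then a golden-section search refines the
    curvature maximum inside that bracket.  ``point_fn(lam)`` must return
    ``(residual, seminorm)``.  Returns ``(lambda, trace, converged)`` where
    trace lists every evaluated ``(lambda, residual, seminorm)``.
    """
    trace: list[tuple[float, float, float]] = []

    def P(lam):
        rho, eta = point_fn(lam)
        trace.append((lam, rho, eta))
        return np.log10(max(rho, 1e-300)), np.log10(max(eta, 1e-300))

    # coarse bracketing scan
    n_scan = 15
    scan_lams = np.logspace(np.log10(lam_lo), np.log10(lam_hi), n_scan)
    scan_pts = [P(lam) for lam in scan_lams]
    curv = np.array(
        [_menger_curvature(scan_pts[i - 1], scan_pts[i], scan_pts[i + 1])
         for i in range(1, n_scan - 1)]
    )
    if np.any(curv > 0):
        i_best = int(np.argmax(curv)) + 1
        lam_lo = scan_lams[max(i_best - 1, 0)]
        lam_hi = scan_lams[min(i_best + 1, n_scan - 1)]

    l1, l4 = np.log10(lam_lo), np.log10(lam_hi)
    l2 = (l4 + _GOLDEN * l1) / (1.0 + _GOLDEN)
    l3 = l1 + l4 - l2
    lams = [10.0**l for l in (l1, l2, l3, l4)]
    pts = [P(lam) for lam in lams]

    converged = False
    for _ in range(iterations):
        if (lams[3] - lams[0]) / lams[3] < tolerance:
            converged = True
            break
        c2 = _menger_curvature(pts[0], pts[1], pts[2])
        c3 = _menger_curvature(pts[1], pts[2], pts[3])
        # negative curvature at the right triple: the corner is to the left
        while c3 <= 0.0 and (lams[3] - lams[0]) / lams[3] >= tolerance:
            lams[3], pts[3] = lams[2], pts[2]
            lams[2], pts[2] = lams[1], pts[1]
            l1, l4 = np.log10(lams[0]), np.log10(lams[3])
            l2 = (l4 + _GOLDEN * l1) / (1.0 + _GOLDEN)
            lams[1] = 10.0**l2
            pts[1] = P(lams[1])
            c3 = _menger_curvature(pts[1], pts[2], pts[3])
        if c2 > c3:
            lams[3], pts[3] = lams[2], pts[2]
            lams[2], pts[2] = lams[1], pts[1]
            l1, l4 = np.log10(lams[0]), np.log10(lams[3])
            l2 = (l4 + _GOLDEN * l1) / (1.0 + _GOLDEN)
            lams[1] = 10.0**l2
            pts[1] = P(lams[1])
        else:
            lams[0], pts[0] = lams[1], pts[1]
            lams[1], pts[1] = lams[2], pts[2]
            l1, l4 = np.log10(lams[0]), np.log10(lams[3])
            lams[2] = 10.0 ** (l1 + l4 - (l4 + _GOLDEN * l1) / (1.0 + _GOLDEN))
            pts[2] = P(lams[2])
    else:
        warnings.warn("L-curve corner search did not converge; returning best iterate", stacklevel=2)

    c2 = _menger_curvature(pts[0], pts[1], pts[2])
    c3 = _menger_curvature(pts[1], pts[2], pts[3])
    lam = lams[1] if c2 >= c3 else lams[2]
    return lam, trace, converged


def find_corner_lambda(A, K, L, config: RegularizationConfig | None = None,
                       solver: TikhonovSolver | None = None) -> float:
    """Locate the L-curve corner lambda for the stacked system ``A R = K``."""
    config = config or RegularizationConfig()
    if solver is None:
        solver = TikhonovSolver(A, L)
    proj = solver.project(K)
    lo, hi, iters, tol = config.search
    dlo, dhi = solver.default_bracket()
    lo = dlo if lo is None else lo
    hi = dhi if hi is None else hi
    lam, _, _ = _corner_search(lambda l: solver.norms(proj, l), lo, hi, iters, tol)
    return lam


# ---------------------------------------------------------------------------
# Full reconstruction
# ---------------------------------------------------------------------------


def reconstruct(
    A,
    K,
    config: RegularizationConfig | None = None,
    heart: TriangleMesh | None = None,
    L=None,
    solver: TikhonovSolver | None = None,
) -> InverseSolution:
    """Reconstruct epicardial potentials with L-curve-selected lambda.

    In ``global`` mode one lambda is chosen from the time-stacked system and
    applied to every timestep; in ``per_timestep`` mode the corner search is
    repeated per column.  Provide either a heart mesh (to build ``L`` from
    the configured order) or ``L`` directly.
    """
    config = config or RegularizationConfig()
    if L is None:
        if heart is None:
            raise ValueError("provide a heart mesh or an explicit operator L")
        L = regularizer(config.order, heart)
    if solver is None:
        solver = TikhonovSolver(A, L)
    K_mat = _as_matrix(K)
    dt = K.dt if isinstance(K, PotentialField) else 1.0
    t0 = K.t0 if isinstance(K, PotentialField) else 0.0
    proj = solver.project(K_mat)
    lo, hi, iters, tol = config.search
    dlo, dhi = solver.default_bracket()
    lo = dlo if lo is None else lo
    hi = dhi if hi is None else hi

    if config.lambda_mode == "global" or K_mat.shape[1] == 1:
        lam, trace, converged = _corner_search(
            lambda l: solver.norms(proj, l), lo, hi, iters, tol
        )
        X = solver.solve(proj, lam)
        residual, seminorm = solver.norms(proj, lam)
        lam_used: float | np.ndarray = lam
    else:
        n_cols = K_mat.shape[1]
        lam_used = np.empty(n_cols)
        residual = np.empty(n_cols)
        seminorm = np.empty(n_cols)
        converged = True
        trace = []
        for j in range(n_cols):
            lam_j, trace_j, conv_j = _corner_search(
                lambda l: solver.norms(proj, l, columns=[j]), lo, hi, iters, tol
            )
            lam_used[j] = lam_j
            converged &= conv_j
            if j == 0:
                trace = trace_j
        X = np.empty((solver.A.shape[1], n_cols))
        for j in range(n_cols):
            X[:, [j]] = solver.solve(
                {"beta": proj["beta"][:, [j]], "perp2": proj["perp2"][[j]],
                 "c": None if proj["c"] is None else proj["c"][:, [j]],
                 "n_cols": 1},
                lam_used[j],
            )
            residual[j], seminorm[j] = solver.norms(proj, lam_used[j], columns=[j])

    return InverseSolution(
        reconstructed=PotentialField(X, dt=dt, t0=t0),
        lambda_used=lam_used,
        residual_norm=residual,
        seminorm=seminorm,
        lcurve_trace=trace,
        converged=bool(converged),
        order=config.order,
        lambda_mode=config.lambda_mode,
    )


# ---------------------------------------------------------------------------
# Model / Results front door
# ---------------------------------------------------------------------------


class EpicardialMapModel:
    """Tikhonov inverse model mapping body-surface to epicardial potentials.

    Parameters
    ----------
    transfer : TransferMatrix or array
        Forward transfer matrix ``A`` (torso nodes x heart nodes).
    bsp : PotentialField or array
        Body-surface potentials ``K`` (torso nodes x timesteps).
    heart : TriangleMesh
        Heart mesh, used to build the regularisation operator.
    order : {0, 1, 2}
        Tikhonov order (identity / gradient / Laplacian penalty).
    lambda_mode : {"global", "per_timestep"}
        One lambda for the stacked system, or one per timestep.
    """

    def __init__(self, transfer, bsp, heart: TriangleMesh, order: int = 2,
                 lambda_mode: str = "global", search=(None, None, 50, 1e-3)):
        self.transfer = transfer
        self.bsp = bsp
        self.heart = heart
        self.config = RegularizationConfig(order=order, lambda_mode=lambda_mode, search=search)
        self.L = regularizer(order, heart)
        self._solver: TikhonovSolver | None = None

    @property
    def solver(self) -> TikhonovSolver:
        if self._solver is None:
            self._solver = TikhonovSolver(self.transfer, self.L)
        return self._solver

    def fit(self, lam: float | None = None) -> "EpicardialMapResults":
        """Solve the inverse problem; ``lam`` overrides the L-curve choice."""
        if lam is None:
            solution = reconstruct(
                self.transfer, self.bsp, self.config, L=self.L, solver=self.solver
            )
        else:
            proj = self.solver.project(_as_matrix(self.bsp))
            X = self.solver.solve(proj, lam)
            residual, seminorm = self.solver.norms(proj, lam)
            dt = self.bsp.dt if isinstance(self.bsp, PotentialField) else 1.0
            t0 = self.bsp.t0 if isinstance(self.bsp, PotentialField) else 0.0
            solution = InverseSolution(
                reconstructed=PotentialField(X, dt=dt, t0=t0),
                lambda_used=lam, residual_norm=residual, seminorm=seminorm,
                order=self.config.order, lambda_mode="fixed",
            )
        return EpicardialMapResults(self, solution)


class EpicardialMapResults:
    """Fitted epicardial reconstruction with diagnostics."""

    def __init__(self, model: EpicardialMapModel, solution: InverseSolution):
        self.model = model
        self.solution = solution

    @property
    def reconstructed(self) -> PotentialField:
        return self.solution.reconstructed

    @property
    def lambda_(self):
        return self.solution.lambda_used

    @property
    def residual_norm(self):
        return self.solution.residual_norm

    @property
    def seminorm(self):
        return self.solution.seminorm

    @property
    def lcurve_trace(self):
        return self.solution.lcurve_trace

    def rdms(self, truth: PotentialField, mode: str = "spatial"):
        """Reconstruction error versus a ground-truth epicardial field."""
        from .metrics import rdms_summary

        return rdms_summary(truth, self.reconstructed, mode=mode)

    def detect(self, q: float = 0.4, t_detect: float | None = None,
               window: tuple | None = None):
        """Threshold-detect the ischemic region on the reconstruction.

        ``window`` (ms) restricts the automatic contrast-maximising timestep
        search, e.g. to the post-activation plateau.
        """
        from .metrics import detect_ischemia

        return detect_ischemia(self.reconstructed, self.model.heart, q=q,
                               t_detect=t_detect, window=window)

    def plot_lcurve(self, ax=None):
        """Log-log L-curve of the evaluated (residual, seminorm) points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        trace = sorted(self.lcurve_trace)
        if trace:
            _, rho, eta = zip(*trace)
            ax.loglog(rho, eta, "o-")
        lam = self.lambda_
        if np.isscalar(lam):
            ax.set_title(f"L-curve (order {self.solution.order}, lambda={lam:.3g})")
        ax.set_xlabel("residual norm ||A r - k||")
        ax.set_ylabel("seminorm ||L r||")
        return ax

    def summary(self) -> str:
        sol = self.solution
        lam = sol.lambda_used
        lines = [
            "Epicardial Map Reconstruction Results",
            "=====================================",
            f"Tikhonov order:     {sol.order}",
            f"lambda mode:        {sol.lambda_mode}",
        ]
        if np.isscalar(lam):
            lines += [
                f"lambda:             {lam:.6g}",
                f"residual norm:      {float(np.atleast_1d(sol.residual_norm)[0]):.6g}",
                f"solution seminorm:  {float(np.atleast_1d(sol.seminorm)[0]):.6g}",
            ]
        else:
            lines += [
                f"lambda (median):    {float(np.median(lam)):.6g}",
                f"lambda (range):     [{lam.min():.3g}, {lam.max():.3g}]",
                f"residual (median):  {float(np.median(sol.residual_norm)):.6g}",
                f"seminorm (median):  {float(np.median(sol.seminorm)):.6g}",
            ]
        lines += [
            f"heart nodes:        {sol.reconstructed.n_nodes}",
            f"timesteps:          {sol.reconstructed.n_steps}",
            f"corner converged:   {sol.converged}",
        ]
        return "\n".join(lines)
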