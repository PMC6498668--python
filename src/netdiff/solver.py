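"""Joint two-condition sparse regression solved by proximal gradient descent.

A gene's incoming edges under two conditions are modelled by a pair of
linear regressions sharing the same predictor set.  The joint objective

    J(beta, beta~) = ||x - X beta||^2 + ||x~ - X~ beta~||^2
                     + lam1 (||beta||_1 + ||beta~||_1)
                     + lam2 ||beta - beta~||_1

is convex; the smooth part is quadratic and the non-smooth part separates
into independent two-variable fused-lasso problems per predictor, each of
which has a closed-form proximal operator (fuse, then soft-threshold).
The iteration is plain proximal gradient with a constant step 1/L, where
L is the Lipschitz constant of the smooth part's gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DesignPair",
    "CoeffPair",
    "SolverConfig",
    "SolverResult",
    "center_columns",
    "soft_threshold",
    "prox_pair",
    "grad_g1",
    "step_size",
    "solve_joint",
    "lasso_cd",
]

_CENTER_TOL = 1e-10


def center_columns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove the column means of ``matrix``.

    Centering absorbs the per-gene intercepts of the regression model, so
    downstream fits are intercept-free.  Returns the centered matrix and
    the vector of removed means.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        matrix = matrix[:, None]
    if matrix.shape[0] < 2:
        raise ValueError("centering requires at least 2 rows")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite entries")
    means = matrix.mean(axis=0)
    return matrix - means, means


@dataclass
class DesignPair:
    """One gene's regression problem under two conditions.

    ``response_*`` hold the (centered) expression of the target gene;
    ``design_*`` hold the centered expression of the remaining genes.  The
    target gene's own column must be absent from both designs.
    """

    response_a: np.ndarray
    design_a: np.ndarray
    response_b: np.ndarray
    design_b: np.ndarray
    predictor_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.response_a = np.asarray(self.response_a, dtype=float).ravel()
        self.response_b = np.asarray(self.response_b, dtype=float).ravel()
        self.design_a = np.asarray(self.design_a, dtype=float)
        self.design_b = np.asarray(self.design_b, dtype=float)
        if self.design_a.ndim != 2 or self.design_b.ndim != 2:
            raise ValueError("designs must be 2-D")
        if self.design_a.shape[1] != self.design_b.shape[1]:
            raise ValueError("designs must share the same predictor columns")
        if self.design_a.shape[0] != self.response_a.size:
            raise ValueError("condition-A design/response sample mismatch")
        if self.design_b.shape[0] != self.response_b.size:
            raise ValueError("condition-B design/response sample mismatch")
        if not self.predictor_labels:
            self.predictor_labels = [f"P{j}" for j in range(self.n_predictors)]
        if len(self.predictor_labels) != self.n_predictors:
            raise ValueError("predictor_labels length mismatch")

    @property
    def n_predictors(self) -> int:
        return self.design_a.shape[1]

    @classmethod
    def from_raw(
        cls,
        response_a: np.ndarray,
        design_a: np.ndarray,
        response_b: np.ndarray,
        design_b: np.ndarray,
        predictor_labels: list[str] | None = None,
    ) -> "DesignPair":
        """Build a centered DesignPair from raw (uncentered) data."""
        ya, _ = center_columns(np.asarray(response_a, dtype=float)[:, None])
        yb, _ = center_columns(np.asarray(response_b, dtype=float)[:, None])
        za, _ = center_columns(design_a)
        zb, _ = center_columns(design_b)
        return cls(ya.ravel(), za, yb.ravel(), zb, predictor_labels or [])


@dataclass
class CoeffPair:
    """Coefficient vectors (beta, beta~) for one gene — one column of B, B~."""

    beta: np.ndarray
    beta_tilde: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.beta_tilde = np.asarray(self.beta_tilde, dtype=float).ravel()
        if self.beta.size != self.beta_tilde.size:
            raise ValueError("beta and beta_tilde must have equal length")
        if not (np.all(np.isfinite(self.beta)) and np.all(np.isfinite(self.beta_tilde))):
            raise ValueError("coefficients must be finite")

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate([self.beta, self.beta_tilde])

    @property
    def delta(self) -> np.ndarray:
        return self.beta - self.beta_tilde


@dataclass
class SolverConfig:
    """Penalties and iteration controls for the joint solver."""

    lam1: float = 0.0
    lam2: float = 0.0
    tol: float = 1e-6
    max_iter: int = 10_000
    step_mode: str = "eigen"

    def __post_init__(self) -> None:
        if self.lam1 < 0 or self.lam2 < 0:
            raise ValueError("penalties must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.step_mode not in ("eigen", "trace"):
            raise ValueError("step_mode must be 'eigen' or 'trace'")


@dataclass
class SolverResult:
    coeffs: CoeffPair
    objective_path: np.ndarray
    n_iter: int
    converged: bool
    step: float
    lipschitz: float


def soft_threshold(x, a):
    """Shrink ``x`` toward zero by ``a``, clipping to zero inside [-a, a]."""
    if np.any(np.asarray(a) < 0):
        raise ValueError("threshold must be nonnegative")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - a, 0.0)
    return float(out) if out.ndim == 0 else out


def prox_pair(t, t_tilde, lam1_eff, lam2_eff):
    """Exact minimizer of the two-variable fused-lasso prox subproblem.

    Minimizes lam1_eff(|b| + |b~|) + lam2_eff|b - b~|
    + ((b - t)^2 + (b~ - t~)^2) / 2 for each coordinate pair.  Solved by
    first fusing the pair toward its midpoint (difference shrunk by
    2*lam2_eff) and then soft-thresholding each component by lam1_eff.
    Accepts scalars or broadcastable arrays for every argument.
    """
    if np.any(np.asarray(lam1_eff) < 0) or np.any(np.asarray(lam2_eff) < 0):
        raise ValueError("effective penalties must be nonnegative")
    t = np.asarray(t, dtype=float)
    t_tilde = np.asarray(t_tilde, dtype=float)
    diff = t - t_tilde
    mid = 0.5 * (t + t_tilde)
    fused = np.abs(diff) <= 2.0 * lam2_eff
    shift = np.where(diff > 0, lam2_eff, -lam2_eff)
    b0 = np.where(fused, mid, t - shift)
    b0_tilde = np.where(fused, mid, t_tilde + shift)
    b = np.sign(b0) * np.maximum(np.abs(b0) - lam1_eff, 0.0)
    b_tilde = np.sign(b0_tilde) * np.maximum(np.abs(b0_tilde) - lam1_eff, 0.0)
    if b.ndim == 0:
        return float(b), float(b_tilde)
    return b, b_tilde


def grad_g1(coeffs: CoeffPair, design: DesignPair) -> np.ndarray:
    """Gradient of the smooth squared-error part, stacked [A-block; B-block]."""
    if coeffs.beta.size != design.n_predictors:
        raise ValueError("coefficient length does not match design")
    ga = 2.0 * (design.design_a.T @ (design.design_a @ coeffs.beta - design.response_a))
    gb = 2.0 * (design.design_b.T @ (design.design_b @ coeffs.beta_tilde - design.response_b))
    return np.concatenate([ga, gb])


def _top_eigenvalue(z: np.ndarray) -> float:
    """Largest eigenvalue of z.T @ z via the smaller Gram side."""
    n, p = z.shape
    gram = z @ z.T if n <= p else z.T @ z
    if not np.any(gram):
        return 0.0
    return float(np.linalg.eigvalsh(gram)[-1])


def step_size(design: DesignPair, mode: str = "eigen") -> tuple[float, float]:
    """Constant proximal-gradient step 1/L for the joint objective.

    ``eigen`` uses L = 2(gamma + gamma~) with gamma the top eigenvalue of
    each condition's Gram matrix (the tight Lipschitz constant); ``trace``
    replaces each eigenvalue by the full trace — cheaper but yields a
    smaller step.
    """
    if mode not in ("eigen", "trace"):
        raise ValueError("mode must be 'eigen' or 'trace'")
    if design.design_a.size == 0 or design.design_b.size == 0:
        raise ValueError("empty design")
    if mode == "eigen":
        lip = 2.0 * (_top_eigenvalue(design.design_a) + _top_eigenvalue(design.design_b))
    else:
        lip = 2.0 * (
            float(np.sum(design.design_a**2)) + float(np.sum(design.design_b**2))
        )
    if lip <= 0:
        raise ValueError("all-zero designs admit no valid step size")
    return 1.0 / lip, lip


def objective(coeffs: CoeffPair, design: DesignPair, lam1: float, lam2: float) -> float:
    """Joint objective J (sum of squares plus the two l1 penalties)."""
    ra = design.response_a - design.design_a @ coeffs.beta
    rb = design.response_b - design.design_b @ coeffs.beta_tilde
    return float(
        ra @ ra
        + rb @ rb
        + lam1 * (np.abs(coeffs.beta).sum() + np.abs(coeffs.beta_tilde).sum())
        + lam2 * np.abs(coeffs.beta - coeffs.beta_tilde).sum()
    )


def solve_joint(
    design: DesignPair,
    config: SolverConfig,
    init: CoeffPair | None = None,
    keep_objective_path: bool = True,
) -> SolverResult:
    """Proximal-gradient solve of the joint two-condition regression.

    Iterates a gradient step on the squared error followed by the exact
    closed-form prox of the fused-lasso penalty, applied independently to
    each coordinate pair, until the relative change of the stacked
    coefficient vector drops below ``config.tol``.
    """
    p = design.n_predictors
    step, lip = step_size(design, config.step_mode)

    # Gram caching: gradient costs O(p^2) per iteration instead of O(np).
    ga_mat = design.design_a.T @ design.design_a
    gb_mat = design.design_b.T @ design.design_b
    ca = design.design_a.T @ design.response_a
    cb = design.design_b.T @ design.response_b
    ssa = float(design.response_a @ design.response_a)
    ssb = float(design.response_b @ design.response_b)

    if init is None:
        beta = np.zeros(p)
        beta_t = np.zeros(p)
    else:
        beta = init.beta.copy()
        beta_t = init.beta_tilde.copy()

    lam1_eff = config.lam1 * step
    lam2_eff = config.lam2 * step

    def obj(b, bt):
        return (
            ssa - 2.0 * (b @ ca) + b @ (ga_mat @ b)
            + ssb - 2.0 * (bt @ cb) + bt @ (gb_mat @ bt)
            + config.lam1 * (np.abs(b).sum() + np.abs(bt).sum())
            + config.lam2 * np.abs(b - bt).sum()
        )

    path = [obj(beta, beta_t)] if keep_objective_path else []
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        t = beta - step * 2.0 * (ga_mat @ beta - ca)
        t_tilde = beta_t - step * 2.0 * (gb_mat @ beta_t - cb)
        new_beta, new_beta_t = prox_pair(t, t_tilde, lam1_eff, lam2_eff)
        delta = np.linalg.norm(new_beta - beta) ** 2 + np.linalg.norm(new_beta_t - beta_t) ** 2
        denom = max(1.0, np.sqrt(np.linalg.norm(beta) ** 2 + np.linalg.norm(beta_t) ** 2))
        beta, beta_t = new_beta, new_beta_t
        if keep_objective_path:
            path.append(obj(beta, beta_t))
        if np.sqrt(delta) / denom <= config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"proximal gradient did not converge in {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return SolverResult(
        coeffs=CoeffPair(beta, beta_t),
        objective_path=np.asarray(path),
        n_iter=n_iter,
        converged=converged,
        step=step,
        lipschitz=lip,
    )


def _cd_kernel(gram, c, lam_eff, b, kkt_tol, max_sweeps):
    """Cycled CD sweeps on the Gram form; returns (b, converged)."""
    p = c.size
    diag = np.diag(gram).copy()
    gb = gram @ b
    thr = 0.5 * lam_eff
    for _ in range(max_sweeps):
        for j in range(p):
            if diag[j] <= 0.0:
                continue
            rho = c[j] - gb[j] + diag[j] * b[j]
            if rho > thr:
                new = (rho - thr) / diag[j]
            elif rho < -thr:
                new = (rho + thr) / diag[j]
            else:
                new = 0.0
            if new != b[j]:
                step = new - b[j]
                for k in range(p):
                    gb[k] += gram[k, j] * step
                b[j] = new
        # KKT residual of the full objective; grad of smooth part is 2(Gb - c)
        worst = 0.0
        for j in range(p):
            g = 2.0 * (gb[j] - c[j])
            if b[j] > 0.0:
                res = abs(g + lam_eff)
            elif b[j] < 0.0:
                res = abs(g - lam_eff)
            else:
                res = max(abs(g) - lam_eff, 0.0)
            if res > worst:
                worst = res
        if worst <= kkt_tol:
            return b, True
    return b, False


try:  # JIT the sweep kernel when numba is available; pure python otherwise
    from numba import njit as _njit

    _cd_kernel = _njit(cache=True)(_cd_kernel)
except ImportError:  # pragma: no cover
    pass


def lasso_cd(
    response: np.ndarray,
    design: np.ndarray,
    lam: float,
    penalty_scale: float = 1.0,
    kkt_tol: float = 1e-8,
    max_sweeps: int = 100_000,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Cycled coordinate descent for ``||y - Zb||^2 + lam*penalty_scale*||b||_1``.

    Uses the same no-1/n scaling convention as the joint objective.  Runs
    full sweeps over the coordinates until the stationarity (KKT) residual
    of every coordinate is at most ``kkt_tol``.  ``init`` warm-starts the
    coefficients (useful along a decreasing lam path).
    """
    y = np.asarray(response, dtype=float).ravel()
    z = np.asarray(design, dtype=float)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    n, p = z.shape
    if y.size != n:
        raise ValueError("response/design sample mismatch")
    gram = np.ascontiguousarray(z.T @ z)
    c = z.T @ y
    b = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    b, ok = _cd_kernel(gram, c, float(lam * penalty_scale), b, float(kkt_tol), max_sweeps)
    if not ok:
        warnings.warn("lasso coordinate descent hit max_sweeps", RuntimeWarning, stacklevel=2)
    return b
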