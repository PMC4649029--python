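"""Inverse solvers for the ill-posed system A x = b.

Four classical approaches to overdetermined, possibly ill-conditioned
least-squares problems:

* OLS   — ordinary least squares, min ||Ax - b||^2, solved through the SVD
          (equivalent to the normal equations x = (A^T A)^{-1} A^T b on
          well-conditioned input, but numerically stable).
* TSVD  — truncated SVD: the t smallest singular components of A are
          discarded before forming the pseudo-inverse solution.
* TTLS  — truncated total least squares: SVD of the augmented matrix
          [A | b], truncated to rank p - t; accounts for errors in A itself
          (errors-in-variables model (A + dA) x = b + db).
* TIKH  — Tikhonov / ridge regularization, min ||Ax - b||^2 +
          lambda ||x - x0||^2, with lambda chosen by the L-curve corner or
          by k-fold cross-validation.

Shrinkage penalties (LASSO, elastic net) are deliberately absent: the zero
entries of the Jacobian are already fixed by the stoichiometric sparsity
pattern, so shrinking the remaining entries toward zero is counterproductive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .lyap import LinearSystem, SVDFactors
from .models import JacobianMatrix, JacobianPattern

logger = logging.getLogger("invjac")

__all__ = [
    "SolverResult",
    "solve_ols",
    "solve_tsvd",
    "solve_ttls",
    "solve_tikhonov",
    "select_lambda",
    "select_truncation",
    "devectorize",
    "solve",
    "METHODS",
]

METHODS = ("OLS", "TSVD", "TTLS", "TIKH")

#: singular values below rel_threshold * sigma_1 count as numerically zero
#: in the auto truncation rule (double-precision motivated)
DEFAULT_TRUNCATION_THRESHOLD = 1e-8


@dataclass
class SolverResult:
    """Solution of one inverse run, de-vectorized back to Jacobian form."""

    x: np.ndarray
    J_est: JacobianMatrix
    method: str
    hyper: dict = field(default_factory=dict)
    residual_norm: float = 0.0
    solution_norm: float = 0.0
    kappa_A: float = np.nan

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "hyper": {k: (v if np.isscalar(v) else np.asarray(v).tolist())
                      for k, v in self.hyper.items()},
            "residual_norm": self.residual_norm,
            "solution_norm": self.solution_norm,
            "kappa_A": None if not np.isfinite(self.kappa_A) else self.kappa_A,
        }
        return json.dumps(payload, indent=2)


def devectorize(x: np.ndarray, pattern: JacobianPattern) -> JacobianMatrix:
    """Place the p-vector x at the pattern positions; exact zeros elsewhere."""
    x = np.asarray(x, dtype=float)
    if x.shape != (pattern.p,):
        raise ValueError(f"x length {x.shape} != pattern p = {pattern.p}")
    J = np.zeros((pattern.n, pattern.n))
    for val, (i, j) in zip(x, pattern.index_map):
        J[i, j] = val
    return JacobianMatrix(
        entries=J, species_ids=[f"S{i + 1}" for i in range(pattern.n)]
    )


def _pattern_of(sys: LinearSystem) -> JacobianPattern:
    n = sys.n
    mask = np.zeros((n, n), dtype=bool)
    for i, j in sys.index_map:
        mask[i, j] = True
    return JacobianPattern(mask=mask)


def _result(sys: LinearSystem, x: np.ndarray, method: str, hyper: dict,
            x0: np.ndarray | None = None) -> SolverResult:
    x0 = np.zeros(sys.p) if x0 is None else np.asarray(x0, dtype=float)
    return SolverResult(
        x=x,
        J_est=devectorize(x, _pattern_of(sys)),
        method=method,
        hyper=hyper,
        residual_norm=float(np.linalg.norm(sys.A @ x - sys.b)),
        solution_norm=float(np.linalg.norm(x - x0)),
        kappa_A=sys.kappa_A,
    )


# ---------------------------------------------------------------------------
# the four solvers
# ---------------------------------------------------------------------------


def solve_ols(sys: LinearSystem) -> SolverResult:
    """Ordinary least squares via the SVD (minimum-norm if rank-deficient)."""
    x, _res, rank, _s = np.linalg.lstsq(sys.A, sys.b, rcond=None)
    if rank < sys.p:
        logger.warning(
            "A is rank-deficient (rank %d < p=%d); minimum-norm OLS returned",
            rank, sys.p,
        )
    return _result(sys, x, "OLS", {})


def solve_tsvd(
    sys: LinearSystem,
    truncation: int | str = "auto",
    rel_threshold: float = DEFAULT_TRUNCATION_THRESHOLD,
) -> SolverResult:
    """Truncated-SVD solution keeping the p - t largest singular components."""
    f = sys.svd()
    t = (
        select_truncation(f, rel_threshold)
        if truncation == "auto"
        else int(truncation)
    )
    if not 0 <= t < sys.p:
        raise ValueError(f"truncation t={t} must satisfy 0 <= t < p={sys.p}")
    k = sys.p - t
    s = f.singular_values[:k]
    coef = (f.U[:, :k].T @ sys.b) / s
    x = f.V[:, :k] @ coef
    return _result(sys, x, "TSVD", {"t": t})


def solve_ttls(
    sys: LinearSystem,
    truncation: int | str = "auto",
) -> SolverResult:
    """Truncated total least squares on the augmented matrix [A | b].

    SVD of [A | b] = U S V^T with V of size (p+1) x (p+1); at kept rank
    k = p - t the solution is the closed form x = -V12 V22^+ with
    V12 = V[:p, k:], V22 = V[p, k:].  Auto mode selects t by k-fold
    cross-validation on held-out equations.
    """
    if truncation == "auto":
        t = _select_ttls_truncation(sys)
    else:
        t = int(truncation)
    if not 0 <= t < sys.p:
        raise ValueError(f"truncation t={t} must satisfy 0 <= t < p={sys.p}")
    x = _ttls_x(sys.A, sys.b, t)
    return _result(sys, x, "TTLS", {"t": t})


def _ttls_x(A: np.ndarray, b: np.ndarray, t: int) -> np.ndarray:
    p = A.shape[1]
    aug = np.column_stack([A, b])
    _U, _s, Vt = np.linalg.svd(aug, full_matrices=True)
    V = Vt.T  # (p+1) x (p+1), includes the null space for fat systems
    k = p - t
    V12 = V[:p, k:]
    V22 = V[p, k:]
    denom = float(V22 @ V22)
    if denom < 1e-30:
        raise ValueError(
            "TTLS V22 block is numerically singular; try a different truncation"
        )
    return -V12 @ V22 / denom


def _select_ttls_truncation(sys: LinearSystem, folds: int = 5, seed: int = 0) -> int:
    """Pick the TTLS truncation level by k-fold cross-validation.

    Plain TLS (t = 0) is near-singular whenever the smallest singular value
    of A is close to the TLS residual, so a data-driven t is essential; the
    held-out prediction error is minimized over all admissible t (ties break
    toward the smaller t, i.e. the least truncation).  Deterministic fold
    assignment.
    """
    # consistent (noiseless) regime: the TLS residual sigma_{p+1}([A|b]) is
    # at rounding level, TLS is exact, and the least truncation is correct
    s_aug = np.linalg.svd(np.column_stack([sys.A, sys.b]), compute_uv=False)
    s_resid = s_aug[sys.p] if s_aug.size > sys.p else 0.0
    if s_resid < 1e-10 * s_aug[0]:
        s_A = np.linalg.svd(sys.A, compute_uv=False)
        return min(
            int(np.sum(s_A < DEFAULT_TRUNCATION_THRESHOLD * s_A[0])), sys.p - 1
        )
    m = sys.A.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    fold_ids = np.array_split(order, folds)
    scores = np.full(sys.p, np.inf)
    for t in range(sys.p):
        total, ok = 0.0, True
        for fold in fold_ids:
            mask = np.ones(m, dtype=bool)
            mask[fold] = False
            try:
                x = _ttls_x(sys.A[mask], sys.b[mask], t)
            except ValueError:
                ok = False
                break
            total += float(np.mean((sys.A[fold] @ x - sys.b[fold]) ** 2))
        if ok:
            scores[t] = total
    if not np.any(np.isfinite(scores)):
        return 0
    return int(np.argmin(scores))


def solve_tikhonov(
    sys: LinearSystem, lam: float, x0: np.ndarray | None = None
) -> SolverResult:
    """Ridge solution of min ||Ax - b||^2 + lambda ||x - x0||_2^2.

    Solved through the augmented stack [A; sqrt(lambda) I] x =
    [b; sqrt(lambda) x0], which keeps the normal-equations convention
    (A^T A + lambda I) x = A^T b + lambda x0 without forming A^T A.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    x0 = np.zeros(sys.p) if x0 is None else np.asarray(x0, dtype=float)
    if x0.shape != (sys.p,):
        raise ValueError("x0 length must equal p")
    x = _tikhonov_x(sys.A, sys.b, lam, x0)
    return _result(sys, x, "TIKH", {"lambda": float(lam), "x0": x0}, x0=x0)


def _tikhonov_x(A: np.ndarray, b: np.ndarray, lam: float, x0: np.ndarray) -> np.ndarray:
    if lam == 0:
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        return x
    rootl = np.sqrt(lam)
    p = A.shape[1]
    Aaug = np.vstack([A, rootl * np.eye(p)])
    baug = np.concatenate([b, rootl * x0])
    x, *_ = np.linalg.lstsq(Aaug, baug, rcond=None)
    return x


# ---------------------------------------------------------------------------
# hyperparameter selection
# ---------------------------------------------------------------------------


def select_truncation(factors: SVDFactors, rel_threshold: float) -> int:
    """t = number of singular values with sigma_i / sigma_1 < rel_threshold."""
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    s = factors.singular_values
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s / s[0] < rel_threshold))


def default_lambda_grid(sys: LinearSystem, size: int = 30) -> np.ndarray:
    """log-spaced grid spanning [sigma_p^2, sigma_1^2] of A."""
    s = np.linalg.svd(sys.A, compute_uv=False)
    smax = s.max()
    smin = s[s > smax * 1e-300].min()
    return np.logspace(np.log10(smin**2), np.log10(smax**2), size)


def select_lambda(
    sys: LinearSystem,
    x0: np.ndarray | None = None,
    method: str = "lcurve",
    grid: np.ndarray | None = None,
    cv_folds: int = 5,
    cv_seed: int = 0,
) -> float:
    """Pick the Tikhonov lambda from a grid by L-curve corner or k-fold CV.

    lcurve: lambda maximizing the discrete curvature of the
    (log residual norm, log solution norm) curve along the grid; the
    standard Tikhonov monotonicity (residual non-decreasing, ||x - x0||
    non-increasing in lambda) is verified as a precondition.  cv: lambda
    minimizing the mean held-out ||A_test x - b_test||^2 over seeded row
    folds.  Ties break toward the smaller lambda.
    """
    grid = default_lambda_grid(sys) if grid is None else np.asarray(grid, float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) < 0):
        raise ValueError("grid must be non-empty, positive and sorted ascending")
    if grid.size == 1:
        logger.warning("single-candidate lambda grid; returning it")
        return float(grid[0])
    x0 = np.zeros(sys.p) if x0 is None else np.asarray(x0, dtype=float)

    if method == "lcurve":
        res = np.empty(grid.size)
        sol = np.empty(grid.size)
        for i, lam in enumerate(grid):
            x = _tikhonov_x(sys.A, sys.b, lam, x0)
            res[i] = float(np.linalg.norm(sys.A @ x - sys.b))
            sol[i] = float(np.linalg.norm(x - x0))
        tol = 1e-8 * max(res.max(), 1.0)
        if np.any(np.diff(res) < -tol) or np.any(np.diff(sol) > tol):
            logger.warning("Tikhonov L-curve monotonicity violated beyond tolerance")
        eps = np.finfo(float).tiny
        lx, ly = np.log(res + eps), np.log(sol + eps)
        # discrete curvature with the grid index as the curve parameter
        dx, dy = np.gradient(lx), np.gradient(ly)
        ddx, ddy = np.gradient(dx), np.gradient(dy)
        curv = (dx * ddy - dy * ddx) / np.power(dx**2 + dy**2 + eps, 1.5)
        best = int(np.argmax(curv))  # argmax returns the first (smallest lambda) tie
        return float(grid[best])

    if method == "cv":
        rng = np.random.default_rng(cv_seed)
        m = sys.A.shape[0]
        order = rng.permutation(m)
        folds = np.array_split(order, cv_folds)
        scores = np.zeros(grid.size)
        for fold in folds:
            mask = np.ones(m, dtype=bool)
            mask[fold] = False
            for i, lam in enumerate(grid):
                x = _tikhonov_x(sys.A[mask], sys.b[mask], lam, x0)
                scores[i] += float(np.mean((sys.A[fold] @ x - sys.b[fold]) ** 2))
        best = int(np.argmin(scores))
        return float(grid[best])

    raise ValueError(f"unknown selection method {method!r}")


def solve(
    sys: LinearSystem,
    method: str,
    truncation: int | str = "auto",
    lam: float | str = "auto",
    x0: np.ndarray | None = None,
    lambda_method: str = "cv",
) -> SolverResult:
    """Dispatch to one of the four solvers with auto hyperparameters."""
    method = method.upper()
    if method == "OLS":
        return solve_ols(sys)
    if method == "TSVD":
        return solve_tsvd(sys, truncation)
    if method == "TTLS":
        return solve_ttls(sys, truncation)
    if method == "TIKH":
        lam_val = (
            select_lambda(sys, x0, method=lambda_method)
            if lam == "auto"
            else float(lam)
        )
        return solve_tikhonov(sys, lam_val, x0)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
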