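"""Lyapunov-equation core.

For a stable Jacobian J and fluctuation matrix D, the stationary covariance
C of the linearized Langevin dynamics solves

    J C + C J^T = -2 D.

The forward direction (J, D -> C) is the ground-truth oracle; the inverse
direction is recast as an overdetermined linear system A x = b where x holds
the p Jacobian entries allowed by the stoichiometric sparsity pattern.  Each
of the n^2 scalar equations (i, k) reads

    sum_j J_ij C_jk + sum_j C_ij J_kj = -2 D_ik

so the coefficient of unknown J_ab in equation (i, k) is
[a = i] C_bk + [a = k] C_ib.  All n^2 rows are kept (the (i, k) and (k, i)
rows coincide when D is symmetric); the conditioning of A — kappa_A =
sigma_1 / sigma_p — is the central diagnostic of the inverse problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .models import JacobianMatrix, JacobianPattern
from .sde import CovarianceEstimate, FluctuationSpec

logger = logging.getLogger("invjac")

__all__ = [
    "LinearSystem",
    "SVDFactors",
    "solve_lyapunov_forward",
    "build_linear_system",
    "condition_number",
    "lyapunov_residual",
]


@dataclass
class SVDFactors:
    """SVD A = U diag(s) V^T with s non-increasing and non-negative."""

    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=float)
        if np.any(s < 0) or np.any(np.diff(s) > 0):
            raise ValueError("singular values must be non-negative, non-increasing")
        self.singular_values = s


@dataclass
class LinearSystem:
    """The sparse-constrained linear form of the Lyapunov equation."""

    A: np.ndarray  # n^2 x p
    b: np.ndarray  # n^2
    index_map: list[tuple[int, int]]  # p unknown Jacobian positions, row-major
    row_map: list[tuple[int, int]]  # n^2 equation positions, row-major
    kappa_A: float  # sigma_1 / sigma_p (inf if rank-deficient)
    kappa_A_finite: float  # ratio to smallest *non-zero* sigma (plottable)

    def __post_init__(self) -> None:
        if self.A.shape != (len(self.row_map), len(self.index_map)):
            raise ValueError("A shape inconsistent with index/row maps")
        if self.b.shape != (len(self.row_map),):
            raise ValueError("b length must be n^2")

    @property
    def p(self) -> int:
        return len(self.index_map)

    @property
    def n(self) -> int:
        return int(round(np.sqrt(len(self.row_map))))

    def svd(self) -> SVDFactors:
        U, s, Vt = np.linalg.svd(self.A, full_matrices=False)
        return SVDFactors(U=U, singular_values=s, V=Vt.T)


def solve_lyapunov_forward(
    J: JacobianMatrix | np.ndarray, D: FluctuationSpec | np.ndarray
) -> CovarianceEstimate:
    """Unique symmetric C with J C + C J^T = -2 D for Hurwitz-stable J.

    Uses the Bartels-Stewart solver; raises for unstable J (no stationary
    covariance exists).
    """
    Jm = J.entries if isinstance(J, JacobianMatrix) else np.asarray(J, dtype=float)
    Dm = D.D if isinstance(D, FluctuationSpec) else np.asarray(D, dtype=float)
    if not np.allclose(Dm, Dm.T):
        raise ValueError("D must be symmetric for the forward solve")
    if np.max(np.real(np.linalg.eigvals(Jm))) >= 0:
        raise ValueError("J is not Hurwitz-stable: no stationary covariance")
    C = scipy.linalg.solve_continuous_lyapunov(Jm, -2.0 * Dm)
    C = (C + C.T) / 2.0
    resid = np.linalg.norm(Jm @ C + C @ Jm.T + 2.0 * Dm) / max(
        np.linalg.norm(2.0 * Dm), np.finfo(float).tiny
    )
    if resid > 1e-10:
        logger.warning("forward Lyapunov solve residual %.3g exceeds 1e-10", resid)
    ids = J.species_ids if isinstance(J, JacobianMatrix) else []
    return CovarianceEstimate(C=C, N_used=0, delta_C=0.0, species_ids=list(ids))


def build_linear_system(
    C: CovarianceEstimate | np.ndarray,
    D: FluctuationSpec | np.ndarray,
    pattern: JacobianPattern,
) -> LinearSystem:
    """Assemble A (n^2 x p) and b (n^2) from C, D and the sparsity pattern.

    Column order follows ``pattern.index_map`` (row-major), row order is
    row-major over equation positions (i, k); b = -2 vec(D).  kappa_A is
    computed from the singular values of A.
    """
    Cm = C.C if isinstance(C, CovarianceEstimate) else np.asarray(C, dtype=float)
    Dm = D.D if isinstance(D, FluctuationSpec) else np.asarray(D, dtype=float)
    n = Cm.shape[0]
    if Dm.shape != (n, n):
        raise ValueError("C and D dimensions disagree")
    if pattern.n != n:
        raise ValueError(
            f"pattern is {pattern.n}x{pattern.n} but C is {n}x{n}"
        )
    p = pattern.p
    if p < 1:
        raise ValueError("pattern has no unknowns")
    if p > n * n:
        raise ValueError("pattern has more unknowns than equations")
    if p > n * (n + 1) // 2:
        logger.warning(
            "p=%d exceeds n(n+1)/2=%d: system is no longer overdetermined",
            p,
            n * (n + 1) // 2,
        )
    A = np.zeros((n * n, p))
    for col, (a, b_) in enumerate(pattern.index_map):
        contrib = np.zeros((n, n))
        contrib[a, :] += Cm[b_, :]  # [a = i] C_bk  for equations (a, k)
        contrib[:, a] += Cm[:, b_]  # [a = k] C_ib  for equations (i, a)
        A[:, col] = contrib.ravel()
    b = -2.0 * Dm.ravel()
    s = np.linalg.svd(A, compute_uv=False)
    kappa, kappa_finite = _kappas(s)
    row_map = [(i, k) for i in range(n) for k in range(n)]
    return LinearSystem(
        A=A,
        b=b,
        index_map=list(pattern.index_map),
        row_map=row_map,
        kappa_A=kappa,
        kappa_A_finite=kappa_finite,
    )


def _kappas(s: np.ndarray) -> tuple[float, float]:
    s = np.asarray(s, dtype=float)
    smax = s.max(initial=0.0)
    if smax == 0.0:
        return np.inf, np.inf
    nonzero = s[s > smax * 1e-300]
    kappa_finite = float(smax / nonzero.min())
    kappa = kappa_finite if nonzero.size == s.size else np.inf
    return kappa, kappa_finite


def condition_number(M: np.ndarray) -> float:
    """sigma_1 / sigma_min; +inf when M is (numerically) rank-deficient.

    Rank deficiency is declared when sigma_min < sigma_1 * 1e-300, i.e. only
    for exact zeros at double precision — large-but-finite ratios are
    reported as-is so ill-conditioning remains quantifiable.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.size == 0:
        raise ValueError("empty matrix")
    s = np.linalg.svd(M, compute_uv=False)
    smax = s.max(initial=0.0)
    if smax == 0.0 or s.min() < smax * 1e-300:
        return np.inf
    return float(smax / s.min())


def lyapunov_residual(
    J: JacobianMatrix | np.ndarray,
    C: CovarianceEstimate | np.ndarray,
    D: FluctuationSpec | np.ndarray,
) -> float:
    """||J C + C J^T + 2D||_F / ||2D||_F.

    Diagnoses how well a candidate Jacobian explains an observed covariance
    under fluctuation D.  A zero D makes the relative form undefined; the
    unnormalized residual is then returned (with a log notice).
    """
    Jm = J.entries if isinstance(J, JacobianMatrix) else np.asarray(J, dtype=float)
    Cm = C.C if isinstance(C, CovarianceEstimate) else np.asarray(C, dtype=float)
    Dm = D.D if isinstance(D, FluctuationSpec) else np.asarray(D, dtype=float)
    num = np.linalg.norm(Jm @ Cm + Cm @ Jm.T + 2.0 * Dm)
    den = np.linalg.norm(2.0 * Dm)
    if den == 0.0:
        logger.info("||D|| = 0: returning unnormalized Lyapunov residual")
        return float(num)
    return float(num / den)
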