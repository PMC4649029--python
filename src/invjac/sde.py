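"""Langevin simulation and stationary covariance estimation.

The deterministic network dS/dt = f(S) is turned into the chemical Langevin
equation dS = f(S) dt + B dW with constant diffusion B B^T = 2D.  Near a
stable steady state the linearized system is an Ornstein-Uhlenbeck process
whose stationary covariance C solves the Lyapunov equation

    J C + C J^T = -2 D,

which is exactly the relation the inverse-Jacobian pipeline exploits.  The
factor 2 in B B^T = 2D is forced by that convention: with it, the empirical
ensemble covariance converges to the forward Lyapunov solution.

Ensembles follow the replicated-experiment design: N independent
realizations are started at the steady state, integrated past the slowest
relaxation time, and the N end-points are the "samples" from which the
metabolomics covariance matrix is estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import KineticModel, SteadyState, find_steady_state, numerical_jacobian, ode_rhs

logger = logging.getLogger("invjac")

__all__ = [
    "FluctuationSpec",
    "EnsembleSamples",
    "CovarianceEstimate",
    "default_fluctuation",
    "simulate_sde",
    "ensemble_covariance",
    "default_timescales",
]


@dataclass
class FluctuationSpec:
    """Fluctuation (diffusion-strength) matrix D.

    Units concentration^2 / time.  The control-condition D0 is diagonal with
    non-negative diagonal (no cross-talk between metabolite fluctuations);
    perturbed versions carry their generation noise level ``sigma_level`` and
    relative Frobenius change ``delta_D``.
    """

    D: np.ndarray
    is_diagonal: bool = True
    sigma_level: float = 0.0
    delta_D: float = 0.0

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise ValueError("D must be square")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("D must be finite")
        if self.sigma_level == 0.0:
            if not np.allclose(self.D, np.diag(np.diag(self.D))):
                raise ValueError("control-condition D0 must be diagonal")
            if np.any(np.diag(self.D) < 0):
                raise ValueError("control-condition D0 must have non-negative diagonal")
            self.is_diagonal = True

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass
class EnsembleSamples:
    """End-of-run concentrations of N independent SDE realizations."""

    samples: np.ndarray  # N x n
    model_id: str
    seed: int
    burn_in_time: float
    dt: float
    n_clipped: int = 0
    n_diverged: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 2:
            raise ValueError("need at least two sample rows")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def N(self) -> int:
        return self.samples.shape[0]


@dataclass
class CovarianceEstimate:
    """Symmetric covariance matrix of metabolite concentrations.

    Units concentration^2.  ``delta_C`` is the relative Frobenius change
    against the reference C0 (0 for C0 itself).
    """

    C: np.ndarray
    N_used: int = 0
    delta_C: float = 0.0
    species_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        self.C = (C + C.T) / 2.0  # exact symmetry by construction
        if self.delta_C < 0:
            raise ValueError("delta_C must be non-negative")

    @property
    def n(self) -> int:
        return self.C.shape[0]

    @property
    def positive_definite(self) -> bool:
        try:
            np.linalg.cholesky(self.C)
            return True
        except np.linalg.LinAlgError:
            return False


def default_fluctuation(
    steady_state: np.ndarray, rho: float = 0.05
) -> FluctuationSpec:
    """Control-condition D0 = diag((rho * S*_i)^2).

    ``rho`` scales the fluctuation amplitude to a fraction of each
    steady-state concentration, keeping the dynamics in the linear-response
    regime where the Lyapunov relation holds.
    """
    s = np.asarray(steady_state, dtype=float)
    return FluctuationSpec(D=np.diag((rho * s) ** 2))


def default_timescales(
    J: np.ndarray, dt_cap: float = 0.05, burn_in_cap: float = 200.0
) -> tuple[float, float]:
    """(dt, burn_in) from the Jacobian spectrum.

    dt resolves the fastest relaxation (0.01 / max|Re eig|, capped), burn_in
    covers ten times the slowest one (10 / min|Re eig|, capped so ensemble
    runs stay tractable for stiff models).
    """
    re = np.abs(np.real(np.linalg.eigvals(np.asarray(J, dtype=float))))
    re = re[re > 0]
    if re.size == 0:
        raise ValueError("Jacobian has no decaying modes")
    dt = min(0.01 / re.max(), dt_cap)
    burn_in = min(10.0 / re.min(), burn_in_cap)
    return float(dt), float(burn_in)


def _diffusion_factor(D: FluctuationSpec) -> np.ndarray:
    """B with B B^T = 2 D; error if 2D is not PSD."""
    M = 2.0 * (D.D + D.D.T) / 2.0
    if D.is_diagonal and np.allclose(M, np.diag(np.diag(M))):
        d = np.diag(M).copy()
        if np.any(d < -1e-15 * max(1.0, np.abs(d).max())):
            raise ValueError("D has negative diagonal; diffusion undefined")
        return np.diag(np.sqrt(np.clip(d, 0.0, None)))
    w, V = np.linalg.eigh(M)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError("D is not positive semi-definite; cannot factor diffusion")
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _euler_maruyama(
    model: KineticModel,
    B: np.ndarray,
    start: np.ndarray,
    t_end: float,
    dt: float,
    rng: np.random.Generator,
    record: bool,
    clip: bool = True,
    blowup: float = 1e9,
):
    """Batched Euler-Maruyama; ``start`` is (m, n).

    Concentration states get a reflecting clip at 0 (``clip``); abstract
    linear test systems run unclipped.
    """
    state = np.array(start, dtype=float)
    m, n = state.shape
    n_steps = int(np.ceil(t_end / dt))
    noisy = np.any(B != 0)
    traj = np.empty((n_steps + 1, m, n)) if record else None
    if record:
        traj[0] = state
    n_clipped = 0
    sqdt = np.sqrt(dt)
    alive = np.ones(m, dtype=bool)
    for k in range(n_steps):
        drift = ode_rhs(model, state)
        state = state + drift * dt
        if noisy:
            dW = rng.standard_normal((m, n)) * sqdt
            state = state + dW @ B.T
        if clip:
            neg = state < 0
            if neg.any():
                n_clipped += int(neg.sum())
                state = np.where(neg, 0.0, state)
        bad = ~np.all(np.isfinite(state), axis=1) | (
            np.linalg.norm(state, axis=1) > blowup
        )
        if bad.any():
            alive &= ~bad
            state[bad] = 0.0  # frozen; flagged via `alive`
            if not alive.any():
                raise RuntimeError(
                    f"all SDE realizations diverged by t={(k + 1) * dt:.4g}"
                )
        if record:
            traj[k + 1] = state
    if n_clipped:
        logger.info(
            "non-negativity clip triggered %d times (%.3g%% of proposals)",
            n_clipped,
            100.0 * n_clipped / (n_steps * m * n),
        )
    return state, alive, n_clipped, traj


def simulate_sde(
    model: KineticModel,
    D: FluctuationSpec,
    start: np.ndarray,
    t_end: float,
    dt: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One Euler-Maruyama trajectory of dS = f(S) dt + B dW, B B^T = 2D.

    Returns (times, trajectory) with trajectory shape (n_steps + 1, n).
    Negative excursions are clipped at zero (concentrations); the run is
    reproducible for a given seed.  Numeric blow-up raises with the failure
    time.
    """
    if dt <= 0 or t_end < dt:
        raise ValueError("need dt > 0 and t_end >= dt")
    B = _diffusion_factor(D)
    rng = np.random.default_rng(seed)
    start = np.asarray(start, dtype=float)[None, :]
    state, alive, _, traj = _euler_maruyama(
        model, B, start, t_end, dt, rng, record=True, clip=model.non_negative
    )
    if not alive[0]:
        raise RuntimeError("SDE trajectory diverged")
    times = np.arange(traj.shape[0]) * dt
    return times, traj[:, 0, :]


def ensemble_covariance(
    model: KineticModel,
    D: FluctuationSpec,
    N: int,
    burn_in: float | None = None,
    dt: float | None = None,
    seed: int = 0,
    steady_state: SteadyState | None = None,
) -> tuple[EnsembleSamples, CovarianceEstimate]:
    """Stationary covariance from N independent realizations.

    Each realization starts at the steady state and runs for ``burn_in``
    time; the covariance of the N end-points is returned with the unbiased
    (N-1) denominator and exact symmetrization.  Diverged realizations are
    excluded and counted; more than 10% divergence is an error.  ``dt`` and
    ``burn_in`` default to the spectrum-derived timescales of the model.
    """
    if N < 2:
        raise ValueError("need N >= 2 realizations")
    if steady_state is None:
        steady_state = find_steady_state(model)
    if not steady_state.converged:
        raise ValueError("model has no converged steady state")
    if dt is None or burn_in is None:
        J = numerical_jacobian(model, steady_state.state).entries
        d_dt, d_burn = default_timescales(J)
        dt = d_dt if dt is None else dt
        burn_in = d_burn if burn_in is None else burn_in
    B = _diffusion_factor(D)
    rng = np.random.default_rng(seed)
    start = np.repeat(steady_state.state[None, :], N, axis=0)
    try:
        endpoints, alive, n_clipped, _ = _euler_maruyama(
            model, B, start, burn_in, dt, rng, record=False,
            clip=model.non_negative,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"ensemble simulation failed: {exc}") from exc
    n_diverged = int((~alive).sum())
    if n_diverged > 0.1 * N:
        raise RuntimeError(
            f"{n_diverged}/{N} realizations diverged; model too unstable for "
            "the requested noise level"
        )
    kept = endpoints[alive]
    samples = EnsembleSamples(
        samples=kept,
        model_id=model.model_id,
        seed=seed,
        burn_in_time=float(burn_in),
        dt=float(dt),
        n_clipped=n_clipped,
        n_diverged=n_diverged,
    )
    C = np.cov(kept, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    cov = CovarianceEstimate(
        C=C, N_used=kept.shape[0], delta_C=0.0, species_ids=list(model.species_ids)
    )
    return samples, cov
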