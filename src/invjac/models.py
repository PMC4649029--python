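"""Kinetic reaction-network models.

A metabolic network with n metabolites is a system of ODEs

    dS/dt = STOI . v(S)

where ``STOI`` is the n x r stoichiometric matrix and ``v`` the vector of
reaction rates (mass action, Michaelis-Menten, ...).  The local regulatory
structure of the network is captured by the Jacobian J_ij = d f_i / d S_j
evaluated at an operating point, typically the steady state of the control
condition.  This module provides the model container, ODE/Jacobian
evaluation, steady-state location, derivation of the Jacobian sparsity
pattern from stoichiometry, and a generator of random stable mass-action
networks used as synthetic ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

logger = logging.getLogger("invjac")

__all__ = [
    "KineticModel",
    "JacobianMatrix",
    "JacobianPattern",
    "SteadyState",
    "RateEvaluationError",
    "linear_model",
    "ode_rhs",
    "numerical_jacobian",
    "find_steady_state",
    "pattern_from_stoichiometry",
    "stiffness_ratio",
    "make_random_mass_action_network",
]


class RateEvaluationError(RuntimeError):
    """A rate law produced a non-finite value."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class KineticModel:
    """A kinetic reaction network.

    Parameters
    ----------
    species_ids
        Ordered identifiers of the n dynamic metabolites.  The order fixes
        the row order of the stoichiometric matrix and of every matrix
        (Jacobian, covariance, fluctuation) derived from the model.
    stoichiometry
        n x r signed integer matrix; rows are species, columns reactions.
    rate_laws
        r sympy expressions over the species symbols; parameters are already
        substituted by their numeric values.  Units are arbitrary
        (concentration / time), the algebra is unit-agnostic.
    parameters
        name -> value map kept for provenance (values are already folded
        into ``rate_laws``).
    reversibility
        r booleans; a reversible reaction's rate may depend on its products,
        which widens the Jacobian sparsity pattern.
    modifiers
        Per-reaction list of species ids that regulate the rate without
        stoichiometric participation (allosteric effectors, enzymes).
    initial_state
        n non-negative concentrations used as integration start.
    """

    species_ids: list[str]
    stoichiometry: np.ndarray
    rate_laws: list[sp.Expr]
    parameters: dict[str, float] = field(default_factory=dict)
    reversibility: list[bool] = field(default_factory=list)
    modifiers: list[list[str]] = field(default_factory=list)
    initial_state: np.ndarray | None = None
    model_id: str = "model"
    non_negative: bool = True  # states are concentrations, clipped at 0 in SDEs

    def __post_init__(self) -> None:
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        n, r = self.n_species, self.n_reactions
        if n < 1 or r < 1:
            raise ValueError("model needs at least one species and one reaction")
        if self.stoichiometry.shape != (n, r):
            raise ValueError(
                f"stoichiometry shape {self.stoichiometry.shape} != ({n}, {r})"
            )
        if not self.reversibility:
            self.reversibility = [False] * r
        if not self.modifiers:
            self.modifiers = [[] for _ in range(r)]
        if len(self.reversibility) != r or len(self.modifiers) != r:
            raise ValueError("reversibility/modifiers length must equal reaction count")
        if self.initial_state is None:
            self.initial_state = np.ones(n)
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        known = set(self.species_ids)
        for laws in self.modifiers:
            for m in laws:
                if m not in known:
                    raise ValueError(f"modifier {m!r} is not a model species")
        free = set()
        for expr in self.rate_laws:
            free |= {str(s) for s in expr.free_symbols}
        unknown = free - known
        if unknown:
            raise ValueError(
                f"rate laws reference unknown symbols {sorted(unknown)}; "
                "substitute parameters before building the model"
            )
        self._rate_funcs = None

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.rate_laws)

    def _compiled_rates(self):
        if self._rate_funcs is None:
            syms = [sp.Symbol(s) for s in self.species_ids]
            self._rate_funcs = [
                sp.lambdify(syms, expr, modules="numpy") for expr in self.rate_laws
            ]
        return self._rate_funcs

    def rates(self, state: np.ndarray) -> np.ndarray:
        """Evaluate all reaction rates.

        ``state`` has shape (n,) or (m, n); the result has shape (r,) or
        (m, r) accordingly, so an ensemble of states is evaluated in one call.
        """
        state = np.asarray(state, dtype=float)
        cols = [state[..., j] for j in range(self.n_species)]
        batch_shape = state.shape[:-1]
        out = np.empty(batch_shape + (self.n_reactions,))
        for k, f in enumerate(self._compiled_rates()):
            val = f(*cols)
            out[..., k] = np.broadcast_to(np.asarray(val, dtype=float), batch_shape)
        return out


@dataclass
class JacobianMatrix:
    """n x n Jacobian d f_i / d S_j; entries have units of inverse time."""

    entries: np.ndarray
    species_ids: list[str]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.species_ids)
        if self.entries.shape != (n, n):
            raise ValueError("Jacobian must be square and match species_ids")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("Jacobian contains non-finite entries")


@dataclass
class JacobianPattern:
    """Boolean non-zero pattern of the Jacobian with its vectorization map.

    ``index_map`` lists the p True positions in row-major order; this order
    is the single vectorization convention used by the linear system builder
    and the solvers.
    """

    mask: np.ndarray
    index_map: list[tuple[int, int]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.shape[0] != self.mask.shape[1]:
            raise ValueError("pattern mask must be square")
        expected = [(int(i), int(j)) for i, j in np.argwhere(self.mask)]
        if self.index_map is None:
            self.index_map = expected
        elif [(int(i), int(j)) for i, j in self.index_map] != expected:
            raise ValueError("index_map must list mask's True positions row-major")

    @property
    def p(self) -> int:
        return len(self.index_map)

    @property
    def n(self) -> int:
        return self.mask.shape[0]

    def vectorize(self, J: np.ndarray | JacobianMatrix) -> np.ndarray:
        """Extract the p pattern-true entries in index_map order."""
        M = J.entries if isinstance(J, JacobianMatrix) else np.asarray(J, float)
        return np.array([M[i, j] for i, j in self.index_map])


@dataclass
class SteadyState:
    """Operating point of the control condition."""

    state: np.ndarray
    residual_norm: float
    converged: bool
    tol: float

    def __post_init__(self) -> None:
        if self.converged and self.residual_norm > self.tol:
            raise ValueError("converged steady state must satisfy its tolerance")


# ---------------------------------------------------------------------------
# model construction helpers
# ---------------------------------------------------------------------------


def linear_model(
    M: np.ndarray,
    c: np.ndarray | None = None,
    species_ids: list[str] | None = None,
) -> KineticModel:
    """Model with linear dynamics dS/dt = M.S + c.

    Each row of M plus offset becomes one reaction producing one unit of the
    corresponding species, so the stoichiometry is the identity and the
    Jacobian equals M everywhere.  Used for analytically tractable
    (Ornstein-Uhlenbeck) test systems.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if c is None:
        c = np.zeros(n)
    c = np.asarray(c, dtype=float)
    ids = species_ids or [f"S{i + 1}" for i in range(n)]
    syms = [sp.Symbol(s) for s in ids]
    laws = [
        sp.Add(*[sp.Float(M[i, j]) * syms[j] for j in range(n)], sp.Float(c[i]))
        for i in range(n)
    ]
    # rate i depends on every species with M[i, j] != 0; declare them all as
    # modifiers so the stoichiometric pattern matches the true support
    mods = [[ids[j] for j in range(n) if M[i, j] != 0] for i in range(n)]
    # linear systems are Ornstein-Uhlenbeck test processes on R^n, not
    # concentration dynamics: no non-negativity clip in SDE simulation
    return KineticModel(
        species_ids=ids,
        stoichiometry=np.eye(n),
        rate_laws=laws,
        reversibility=[False] * n,
        modifiers=mods,
        model_id="linear",
        non_negative=False,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def ode_rhs(model: KineticModel, state: np.ndarray) -> np.ndarray:
    """Right-hand side STOI . v(S); supports batched states (m, n)."""
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != model.n_species:
        raise ValueError("state length must equal species count")
    v = model.rates(state)
    if not np.all(np.isfinite(v)):
        bad = np.argwhere(~np.isfinite(np.atleast_2d(v)))[0, -1]
        raise RateEvaluationError(
            f"rate law {bad} of model {model.model_id!r} is non-finite at the "
            "given state"
        )
    return v @ model.stoichiometry.T


def numerical_jacobian(
    model: KineticModel,
    state: np.ndarray,
    rel_step: float = 1e-6,
    abs_floor: float = 1e-8,
) -> JacobianMatrix:
    """Central finite-difference Jacobian of the ODE right-hand side.

    The step for species j is ``rel_step * max(|S_j|, abs_floor / rel_step)``
    so that zero concentrations still get a usable absolute step.
    """
    if rel_step <= 0:
        raise ValueError("rel_step must be positive")
    state = np.asarray(state, dtype=float)
    n = model.n_species
    h = np.maximum(rel_step * np.abs(state), abs_floor)
    # batch the 2n perturbed evaluations into one rates() call
    pts = np.repeat(state[None, :], 2 * n, axis=0)
    for j in range(n):
        pts[2 * j, j] += h[j]
        pts[2 * j + 1, j] -= h[j]
    f = ode_rhs(model, pts)
    J = np.empty((n, n))
    for j in range(n):
        J[:, j] = (f[2 * j] - f[2 * j + 1]) / (2 * h[j])
    return JacobianMatrix(entries=J, species_ids=list(model.species_ids))


def find_steady_state(
    model: KineticModel,
    initial: np.ndarray | None = None,
    tol: float = 1e-9,
    max_time: float = 1e4,
    divergence_bound: float = 1e9,
) -> SteadyState:
    """Integrate the ODE until max |dS/dt| <= tol or max_time is reached.

    Uses a stiff-capable integrator (LSODA) in geometrically growing time
    spans.  Divergence (state norm beyond ``divergence_bound``, or integrator
    failure) yields a non-converged result, never an exception.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    state = np.asarray(
        model.initial_state if initial is None else initial, dtype=float
    ).copy()

    def rhs(_t, y):
        return ode_rhs(model, y)

    t, span = 0.0, 1.0
    while t < max_time:
        span = min(span, max_time - t)
        try:
            sol = solve_ivp(
                rhs, (0.0, span), state, method="LSODA", rtol=1e-10, atol=1e-12
            )
        except (RateEvaluationError, ValueError):
            return SteadyState(state, np.inf, False, tol)
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            return SteadyState(state, np.inf, False, tol)
        state = sol.y[:, -1]
        if np.linalg.norm(state) > divergence_bound:
            return SteadyState(state, np.inf, False, tol)
        t += span
        span *= 4.0
        resid = float(np.max(np.abs(ode_rhs(model, state))))
        if resid <= tol:
            return SteadyState(state, resid, True, tol)
    resid = float(np.max(np.abs(ode_rhs(model, state))))
    return SteadyState(state, resid, resid <= tol, tol)


def pattern_from_stoichiometry(model: KineticModel) -> JacobianPattern:
    """Jacobian sparsity pattern implied by stoichiometry and reversibility.

    Entry (i, j) can be non-zero iff some reaction changes species i
    (stoichiometry != 0) and its rate depends on species j, where a rate is
    taken to depend on its reactants, on its products if the reaction is
    reversible, and on its declared modifiers.  Allosteric regulation that is
    invisible in the stoichiometry must be supplied through ``modifiers``.
    """
    n, r = model.n_species, model.n_reactions
    idx = {s: k for k, s in enumerate(model.species_ids)}
    mask = np.zeros((n, n), dtype=bool)
    for rxn in range(r):
        changed = np.nonzero(model.stoichiometry[:, rxn] != 0)[0]
        influencers = set(np.nonzero(model.stoichiometry[:, rxn] < 0)[0])
        if model.reversibility[rxn]:
            influencers |= set(np.nonzero(model.stoichiometry[:, rxn] > 0)[0])
        influencers |= {idx[m] for m in model.modifiers[rxn]}
        for i in changed:
            for j in influencers:
                mask[i, j] = True
    return JacobianPattern(mask=mask)


def stiffness_ratio(
    J: JacobianMatrix, pattern: JacobianPattern, zero_tol: float = 0.0
) -> float:
    """max|J_ij| / min|J_ij| over pattern-true entries with non-zero value.

    A large ratio signals a wide spread of timescales in the network, which
    degrades both the inverse solution and the R^2 goodness metric.
    """
    vals = np.abs(pattern.vectorize(J))
    vals = vals[vals > zero_tol]
    if vals.size == 0:
        raise ValueError("all pattern entries of the Jacobian are numerically zero")
    return float(vals.max() / vals.min())


# ---------------------------------------------------------------------------
# synthetic network generator
# ---------------------------------------------------------------------------


def _build_candidate(n: int, density: float, rng: np.random.Generator):
    """One random mass-action candidate network (may be unstable)."""
    ids = [f"M{i + 1}" for i in range(n)]
    syms = [sp.Symbol(s) for s in ids]

    def logu(lo=0.2, hi=5.0):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    cols: list[np.ndarray] = []
    laws: list[sp.Expr] = []

    # connected backbone: conversions along a random permutation chain
    perm = rng.permutation(n)
    edges = [(int(perm[i]), int(perm[i + 1])) for i in range(n - 1)]
    n_extra = max(0, int(round(density * n * (n - 1))) - len(edges))
    for _ in range(n_extra):
        a, b = rng.choice(n, size=2, replace=False)
        edges.append((int(a), int(b)))
    for a, b in edges:
        col = np.zeros(n)
        col[a], col[b] = -1, 1
        cols.append(col)
        laws.append(sp.Float(logu()) * syms[a])

    # a couple of bimolecular condensations keep the dynamics non-linear
    n_bi = rng.integers(0, max(1, n // 4) + 1)
    for _ in range(n_bi):
        a, b, c = rng.choice(n, size=3, replace=False)
        col = np.zeros(n)
        col[a] -= 1
        col[b] -= 1
        col[c] += 1
        cols.append(col)
        laws.append(sp.Float(logu(0.2, 2.0)) * syms[a] * syms[b])

    # constant influx into a few entry metabolites
    for a in rng.choice(n, size=max(1, n // 3), replace=False):
        col = np.zeros(n)
        col[a] = 1
        cols.append(col)
        laws.append(sp.Float(logu(0.5, 2.0)))

    # first-order exchange with external pools on every species: keeps the
    # steady-state Jacobian diagonally dominant in columns, hence stable
    for a in range(n):
        col = np.zeros(n)
        col[a] = -1
        cols.append(col)
        laws.append(sp.Float(logu(0.3, 3.0)) * syms[a])

    return KineticModel(
        species_ids=ids,
        stoichiometry=np.column_stack(cols),
        rate_laws=laws,
        model_id=f"synthetic_n{n}",
    )


def make_random_mass_action_network(
    n: int,
    density: float = 0.3,
    seed: int = 0,
    max_retries: int = 60,
    max_kappa: float | None = None,
) -> KineticModel:
    """Random connected mass-action network with a stable steady state.

    Draws uni/bi-molecular conversions with log-uniform rate constants,
    constant influxes, and first-order dilution on every species, then keeps
    the first candidate whose steady state exists (positive, converged), whose
    Jacobian is Hurwitz-stable, and whose stoichiometric pattern leaves the
    Lyapunov system overdetermined (p <= n(n+1)/2).  Fully deterministic for
    a given seed.

    ``max_kappa``, if given, additionally rejects candidates whose
    noise-free linear system has condition number above it.  Random sparse
    networks span many orders of magnitude in conditioning; benchmarking
    protocols that presuppose a well-conditioned model (as real mass-action
    pathway models tend to be, kappa_A ~ 1e3-1e4) request it explicitly.
    """
    if n < 2:
        raise ValueError("need at least two species")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        model = _build_candidate(n, density, rng)
        pattern = pattern_from_stoichiometry(model)
        if pattern.p > n * (n + 1) // 2:
            continue
        ss = find_steady_state(model, tol=1e-9, max_time=1e4)
        if not ss.converged or np.any(ss.state <= 0):
            continue
        J = numerical_jacobian(model, ss.state)
        if np.max(np.real(np.linalg.eigvals(J.entries))) >= 0:
            continue
        if max_kappa is not None:
            from .lyap import build_linear_system, solve_lyapunov_forward
            from .sde import default_fluctuation

            D0 = default_fluctuation(ss.state)
            C0 = solve_lyapunov_forward(J, D0)
            if build_linear_system(C0, D0, pattern).kappa_A > max_kappa:
                continue
        model.initial_state = ss.state
        return model
    raise RuntimeError(
        f"no stable network found in {max_retries} attempts (n={n}, density={density})"
    )
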