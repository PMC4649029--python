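"""Shared fixtures: small hand-built kinetic models and oracles."""

from __future__ import annotations

import numpy as np
import pytest
import sympy as sp
from hypothesis import settings

from invjac import KineticModel, linear_model

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def chain_model() -> KineticModel:
    """Irreversible mass-action chain A -> B -> (sink), k1=2, k2=3."""
    A, B = sp.symbols("A B")
    return KineticModel(
        species_ids=["A", "B"],
        stoichiometry=np.array([[-1, 0], [1, -1]]),
        rate_laws=[2 * A, 3 * B],
        parameters={"k1": 2.0, "k2": 3.0},
        model_id="chain",
    )


@pytest.fixture
def stable_linear_2d() -> KineticModel:
    """dS/dt = M S + c with M = [[-1, 0.3], [0.2, -2]], c = (1, 1)."""
    M = np.array([[-1.0, 0.3], [0.2, -2.0]])
    return linear_model(M, c=np.array([1.0, 1.0]))


def kron_lyapunov_C(J: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Brute-force Kronecker solve of J C + C J^T = -2 D (row-major vec)."""
    n = J.shape[0]
    M = np.kron(J, np.eye(n)) + np.kron(np.eye(n), J)
    return np.linalg.solve(M, -2.0 * D.ravel()).reshape(n, n)


def lyapunov_operator_columns(C: np.ndarray, index_map) -> np.ndarray:
    """Independent construction of A: column (a, b) = vec(E_ab C + C E_ab^T)."""
    n = C.shape[0]
    cols = []
    for a, b in index_map:
        E = np.zeros((n, n))
        E[a, b] = 1.0
        cols.append((E @ C + C @ E.T).ravel())
    return np.column_stack(cols)
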