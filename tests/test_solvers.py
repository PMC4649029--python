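"""The four inverse solvers, hyperparameter selection, de-vectorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invjac import (
    JacobianPattern,
    LinearSystem,
    devectorize,
    select_lambda,
    select_truncation,
    solve_ols,
    solve_tikhonov,
    solve_tsvd,
    solve_ttls,
)
from invjac.lyap import SVDFactors, _kappas


def make_system(A, b):
    """Wrap a raw (A, b) into a LinearSystem with a synthetic index map.

    Rows are zero-padded up to the next square n^2 (zero equations do not
    change any least-squares, TSVD, TLS or ridge solution), so the wrapped
    system has the same layout as one built from an n x n covariance.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    rows, p = A.shape
    n = int(np.ceil(np.sqrt(max(rows, p))))
    pad = n * n - rows
    A = np.vstack([A, np.zeros((pad, p))])
    b = np.concatenate([b, np.zeros(pad)])
    index_map = [(i // n, i % n) for i in range(p)]
    row_map = [(i // n, i % n) for i in range(n * n)]
    kappa, kappa_fin = _kappas(np.linalg.svd(A, compute_uv=False))
    return LinearSystem(A=A, b=b, index_map=index_map, row_map=row_map,
                        kappa_A=kappa, kappa_A_finite=kappa_fin)


class TestOLS:
    def test_identity(self):
        sys = make_system(np.eye(3), [1.0, -2.0, 0.5])
        np.testing.assert_allclose(solve_ols(sys).x, [1.0, -2.0, 0.5])

    def test_mean_of_observations(self):
        sys = make_system([[1.0], [1.0]], [1.0, 3.0])
        assert solve_ols(sys).x[0] == pytest.approx(2.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((12, 4))
        b = rng.standard_normal(12)
        sys = make_system(A, b)
        assert sys.kappa_A < 1e6
        expected = np.linalg.solve(A.T @ A, A.T @ b)
        np.testing.assert_allclose(solve_ols(sys).x, expected, atol=1e-9)


class TestTSVD:
    def test_no_truncation_equals_ols(self):
        rng = np.random.default_rng(1)
        sys = make_system(rng.standard_normal((10, 4)), rng.standard_normal(10))
        np.testing.assert_allclose(
            solve_tsvd(sys, truncation=0).x, solve_ols(sys).x, atol=1e-12
        )

    def test_auto_threshold_drops_tiny_singular_value(self):
        sys = make_system(np.diag([1.0, 1e-12]), [1.0, 1.0])
        x = solve_tsvd(sys, truncation="auto").x
        np.testing.assert_allclose(x, [1.0, 0.0], atol=1e-9)

    def test_rank_one_formula(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((8, 3))
        b = rng.standard_normal(8)
        sys = make_system(A, b)
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        expected = (U[:, 0] @ b / s[0]) * Vt[0]
        np.testing.assert_allclose(
            solve_tsvd(sys, truncation=2).x, expected, atol=1e-12
        )

    def test_invalid_truncation(self):
        sys = make_system(np.eye(2), [1.0, 1.0])
        with pytest.raises(ValueError):
            solve_tsvd(sys, truncation=2)


class TestTTLS:
    def test_consistent_system_equals_ols(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((10, 3))
        x_true = rng.standard_normal(3)
        sys = make_system(A, A @ x_true)
        np.testing.assert_allclose(
            solve_ttls(sys, truncation=0).x, solve_ols(sys).x, atol=1e-8
        )

    def test_scalar(self):
        sys = make_system([[2.0]], [4.0])
        assert solve_ttls(sys, truncation=0).x[0] == pytest.approx(2.0)

    def test_robust_to_errors_in_A(self):
        """Errors-in-variables: TTLS beats OLS on average when A is noisy."""
        rng = np.random.default_rng(4)
        A0 = rng.standard_normal((20, 2))
        x_true = np.array([1.5, -0.7])
        b = A0 @ x_true  # exact b, noise goes into A only
        err_tls, err_ols = [], []
        for _ in range(100):
            A = A0 + 0.3 * rng.standard_normal(A0.shape)
            sys = make_system(A, b)
            err_tls.append(np.linalg.norm(solve_ttls(sys, truncation=0).x - x_true))
            err_ols.append(np.linalg.norm(solve_ols(sys).x - x_true))
        assert np.mean(err_tls) <= np.mean(err_ols)

    def test_auto_on_consistent_system_keeps_full_rank(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((12, 4))
        sys = make_system(A, A @ rng.standard_normal(4))
        assert solve_ttls(sys).hyper["t"] == 0


class TestTikhonov:
    def test_zero_lambda_equals_ols(self):
        rng = np.random.default_rng(6)
        sys = make_system(rng.standard_normal((9, 3)), rng.standard_normal(9))
        np.testing.assert_allclose(
            solve_tikhonov(sys, 0.0).x, solve_ols(sys).x, atol=1e-10
        )

    def test_huge_lambda_returns_prior(self):
        rng = np.random.default_rng(7)
        sys = make_system(rng.standard_normal((9, 3)), rng.standard_normal(9))
        v = np.array([0.3, -1.2, 2.0])
        x = solve_tikhonov(sys, 1e12, x0=v).x
        np.testing.assert_allclose(x, v, rtol=1e-5)

    def test_scalar_closed_form(self):
        sys = make_system([[1.0]], [1.0])
        assert solve_tikhonov(sys, 1.0).x[0] == pytest.approx(0.5)

    def test_negative_lambda_rejected(self):
        sys = make_system(np.eye(2), [1.0, 1.0])
        with pytest.raises(ValueError):
            solve_tikhonov(sys, -1.0)

    def test_monotone_norms_along_grid(self):
        rng = np.random.default_rng(8)
        sys = make_system(rng.standard_normal((20, 5)), rng.standard_normal(20))
        lams = np.logspace(-6, 6, 30)
        res = [solve_tikhonov(sys, lam).residual_norm for lam in lams]
        sol = [solve_tikhonov(sys, lam).solution_norm for lam in lams]
        assert np.all(np.diff(res) >= -1e-9)
        assert np.all(np.diff(sol) <= 1e-9)


class TestHyperparameterSelection:
    def test_single_candidate_grid(self):
        sys = make_system(np.eye(2), [1.0, 1.0])
        assert select_lambda(sys, grid=np.array([0.1])) == pytest.approx(0.1)

    def test_well_conditioned_prefers_small_lambda(self):
        rng = np.random.default_rng(9)
        A = np.vstack([np.eye(4), 0.5 * np.eye(4)])
        x_true = rng.standard_normal(4)
        sys = make_system(A, A @ x_true)
        assert sys.kappa_A < 10
        grid = np.logspace(-8, 2, 21)
        lam = select_lambda(sys, method="cv", grid=grid)
        assert lam <= np.median(grid)

    def test_lcurve_runs_and_returns_grid_member(self):
        rng = np.random.default_rng(10)
        sys = make_system(rng.standard_normal((16, 4)), rng.standard_normal(16))
        grid = np.logspace(-6, 2, 15)
        assert select_lambda(sys, method="lcurve", grid=grid) in grid

    def test_invalid_grid(self):
        sys = make_system(np.eye(2), [1.0, 1.0])
        with pytest.raises(ValueError):
            select_lambda(sys, grid=np.array([-1.0, 1.0]))

    @pytest.mark.parametrize(
        "sigmas,threshold,expected",
        [((1.0, 0.5, 1e-12), 1e-8, 1),
         ((1.0, 1.0, 1.0), 1e-8, 0),
         ((1.0, 1e-3, 1e-6, 1e-9), 1e-5, 2)],
    )
    def test_truncation_count(self, sigmas, threshold, expected):
        f = SVDFactors(U=np.eye(len(sigmas)), singular_values=np.array(sigmas),
                       V=np.eye(len(sigmas)))
        assert select_truncation(f, threshold) == expected


class TestDevectorize:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        mask = rng.random((n, n)) < 0.5
        if not mask.any():
            mask[0, 0] = True
        pat = JacobianPattern(mask)
        x = rng.standard_normal(pat.p)
        J = devectorize(x, pat)
        np.testing.assert_array_equal(pat.vectorize(J), x)
        assert np.all(J.entries[~mask] == 0.0)

    def test_full_pattern_is_row_major_reshape(self):
        pat = JacobianPattern(np.ones((3, 3), dtype=bool))
        x = np.arange(9.0)
        np.testing.assert_array_equal(devectorize(x, pat).entries, x.reshape(3, 3))

    def test_length_mismatch(self):
        pat = JacobianPattern(np.ones((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            devectorize(np.zeros(3), pat)
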