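"""Decomposition solver: prox operators, closed-form updates, ADMM contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.optimize import minimize, minimize_scalar

from sparcoc import (
    decompose_common_vector,
    decompose_multi_condition,
    project_frobenius_ball,
    singular_value_threshold,
    soft_threshold,
    update_background,
)
from _oracles import (
    l1_common_vector_optimum,
    multi_condition_duality_gap,
    nuclear_prox_certificate,
)

finite_matrices = arrays(
    float, (4, 4), elements=st.floats(-10, 10, allow_nan=False, width=32)
)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "A, tau, expected",
        [
            ([[3.0]], 1.0, [[2.0]]),
            ([[-0.5]], 1.0, [[0.0]]),
            ([[-3.0, 0.2], [0.0, 1.5]], 0.5, [[-2.5, 0.0], [0.0, 1.0]]),
        ],
    )
    def test_entrywise_shrinkage(self, A, tau, expected):
        np.testing.assert_allclose(soft_threshold(np.array(A), tau), expected)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones((2, 2)), -0.1)

    def test_matches_scalar_prox_oracle(self, rng):
        """Each entry solves min_y tau*|y| + 0.5*(y-a)^2 (scalar solver)."""
        A = rng.normal(0, 2, size=(4, 4))
        tau = 0.3
        result = soft_threshold(A, tau)
        for a, y in zip(A.ravel(), result.ravel()):
            opt = minimize_scalar(
                lambda t: tau * abs(t) + 0.5 * (t - a) ** 2,
                bounds=(-10, 10), method="bounded",
                options={"xatol": 1e-10},
            )
            assert abs(y - opt.x) < 1e-6

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(A=finite_matrices, tau=st.floats(0, 5))
    def test_never_moves_entry_by_more_than_tau(self, A, tau):
        out = soft_threshold(A, tau)
        assert np.all(np.abs(out - A) <= tau + 1e-12)
        assert np.all(np.abs(out) <= np.abs(A))


class TestProjectFrobeniusBall:
    def test_inside_ball_unchanged(self):
        A = np.array([[3.0, 4.0], [0.0, 0.0]])
        np.testing.assert_array_equal(project_frobenius_ball(A, 10.0), A)

    def test_rescales_to_radius(self):
        A = np.array([[3.0, 4.0], [0.0, 0.0]])
        np.testing.assert_allclose(
            project_frobenius_ball(A, 1.0), [[0.6, 0.8], [0.0, 0.0]]
        )

    def test_zero_radius_gives_zero(self, rng):
        out = project_frobenius_ball(rng.normal(size=(3, 5)), 0.0)
        np.testing.assert_array_equal(out, np.zeros((3, 5)))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(A=finite_matrices, delta=st.floats(0, 20))
    def test_result_always_in_ball(self, A, delta):
        assert np.linalg.norm(project_frobenius_ball(A, delta)) <= delta + 1e-9


class TestUpdateBackground:
    def test_constant_columns_recovered(self, rng):
        v = rng.normal(size=6)
        R = np.tile(v[:, None], (1, 9))
        np.testing.assert_allclose(update_background(R), v)

    def test_row_means(self):
        np.testing.assert_allclose(
            update_background(np.array([[1.0, 3.0], [2.0, 4.0]])), [2.0, 3.0]
        )

    def test_matches_numeric_minimizer(self, rng):
        """x-subproblem optimum agrees with derivative-free minimization."""
        R = rng.normal(size=(5, 7))
        x = update_background(R)
        res = minimize(
            lambda z: 0.5 * ((z[:, None] - R) ** 2).sum(),
            np.zeros(5), method="Powell",
            options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000},
        )
        np.testing.assert_allclose(x, res.x, atol=1e-6)


class TestSingularValueThreshold:
    def test_identity_at_zero_threshold(self, rng):
        A = rng.normal(size=(4, 6))
        np.testing.assert_allclose(singular_value_threshold(A, 0.0), A, atol=1e-10)

    def test_rank_one_shrinks_singular_value(self, rng):
        u = rng.normal(size=5)
        u /= np.linalg.norm(u)
        v = rng.normal(size=4)
        v /= np.linalg.norm(v)
        np.testing.assert_allclose(
            singular_value_threshold(5.0 * np.outer(u, v), 2.0),
            3.0 * np.outer(u, v),
            atol=1e-10,
        )

    def test_nuclear_prox_optimality_certificate(self, rng):
        """A - X must lie in tau * subdifferential of the nuclear norm."""
        A = rng.normal(size=(5, 5))
        X = singular_value_threshold(A, 1.0)
        assert nuclear_prox_certificate(A, X, 1.0) < 1e-8


class TestCommonVectorDecomposition:
    def test_pure_background_gives_zero_foreground(self, rng):
        c = rng.uniform(1, 50, size=8)
        M = np.tile(c[:, None], (1, 12))
        dec = decompose_common_vector(M, delta=0.0, tol=1e-10)
        np.testing.assert_allclose(dec.x, c, atol=1e-6)
        np.testing.assert_allclose(dec.Y, 0.0, atol=1e-6)
        np.testing.assert_allclose(dec.Z, 0.0, atol=1e-8)

    def test_toy_exact_recovery(self, toy, toy_decomposition):
        """delta=0 recovers the planted background and 5x5 block exactly."""
        dec = toy_decomposition
        np.testing.assert_allclose(dec.background, toy.background, atol=1e-5)
        np.testing.assert_allclose(dec.Y, toy.foreground, atol=1e-5)

    def test_objective_matches_convex_optimum_delta0(self):
        """delta=0 objective equals the closed-form row-median optimum.

        (The delta>0 comparison against the generic constrained solver is
        exercised in the acceptance suite; the closed form here is fast.)
        """
        for seed in range(5):
            r = np.random.default_rng(seed)
            M = r.normal(size=(8, 10)) + r.uniform(1, 5, size=(8, 1))
            dec = decompose_common_vector(M, delta=0.0, tol=1e-10, max_iter=50000)
            opt = l1_common_vector_optimum(M)
            assert abs(dec.objective - opt) / max(1.0, opt) < 1e-6

    def test_feasibility_contracts(self, rng):
        M = rng.normal(size=(6, 9)) + 3.0
        for delta in (0.0, 0.4, 2.0):
            dec = decompose_common_vector(M, delta=delta, tol=1e-8, max_iter=50000)
            assert np.linalg.norm(dec.Z) <= delta + 1e-8
            residual = np.linalg.norm(dec.background + dec.Y + dec.Z - M)
            assert residual <= 1e-8 * max(1.0, np.linalg.norm(M))
            assert dec.primal_residual_trace[-1] == pytest.approx(residual)

    def test_delta_monotonicity_of_objective(self, rng):
        """Optimal ||Y||_1 is nonincreasing in the noise budget delta."""
        M = rng.normal(size=(6, 8)) + 2.0
        objs = [
            decompose_common_vector(M, delta=d, tol=1e-9, max_iter=50000).objective
            for d in (0.0, 0.2, 0.5, 1.0, 2.0, 5.0)
        ]
        assert all(a >= b - 1e-6 for a, b in zip(objs, objs[1:]))

    def test_large_delta_degenerate_regime(self, rng):
        """delta beyond the row-mean residual makes Y=0 optimal."""
        M = rng.normal(size=(5, 7))
        resid = np.linalg.norm(M - M.mean(axis=1, keepdims=True))
        dec = decompose_common_vector(M, delta=resid * 1.5, tol=1e-9, max_iter=20000)
        assert dec.objective < 1e-6

    def test_nonconvergence_flagged(self, rng):
        M = rng.normal(size=(6, 8)) + 2.0
        with pytest.warns(UserWarning, match="did not converge"):
            dec = decompose_common_vector(M, delta=0.1, tol=1e-12, max_iter=3)
        assert not dec.converged
        assert dec.iterations == 3

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            decompose_common_vector(np.ones((3, 3)), delta=-1.0)
        with pytest.raises(ValueError):
            decompose_common_vector(np.array([[np.nan, 1.0]]), delta=0.0)


class TestMultiConditionDecomposition:
    def test_zero_input_gives_zero_solution(self):
        res = decompose_multi_condition(
            [np.zeros((4, 5)), np.zeros((4, 5))], [1.0, 1.0], delta=0.0
        )
        np.testing.assert_array_equal(res.X, 0.0)
        for Y in res.Y_list:
            np.testing.assert_array_equal(Y, 0.0)

    def test_objective_near_convex_optimum_by_duality(self):
        """K=1 planted low-rank + sparse: duality gap certifies optimality."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            L = np.outer(r.normal(size=8), r.normal(size=8))
            S = (r.random((8, 8)) < 0.1) * r.normal(0, 5, size=(8, 8))
            M = L + S
            for delta in (0.0, 0.3):
                res = decompose_multi_condition(
                    [M], [0.25], delta=delta, tol=1e-10, max_iter=100000
                )
                assert multi_condition_duality_gap(res, [M]) < 1e-4

    def test_common_vector_constraint_reduces_to_m1(self, toy):
        """With X = x*iota enforced, K=1 coincides with the rank-one solver."""
        dec1 = decompose_common_vector(toy.M, delta=0.0, tol=1e-10, max_iter=20000)
        res = decompose_multi_condition(
            [toy.M.values], [1.0], delta=0.0, tol=1e-10, max_iter=20000,
            common_vector=True,
        )
        np.testing.assert_allclose(res.X, dec1.background, atol=1e-5)
        np.testing.assert_allclose(res.Y_list[0], dec1.Y, atol=1e-5)

    def test_per_condition_feasibility(self, rng):
        mats = [rng.normal(size=(5, 6)) + 1.0 for _ in range(3)]
        res = decompose_multi_condition(
            mats, [0.3, 0.3, 0.3], delta=0.5, tol=1e-8, max_iter=50000
        )
        for M, Y, Z in zip(mats, res.Y_list, res.Z_list):
            assert np.linalg.norm(Z) <= 0.5 + 1e-8
            assert np.linalg.norm(res.X + Y + Z - M) <= 1e-6 * max(
                1.0, np.linalg.norm(M)
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            decompose_multi_condition(
                [np.ones((3, 4)), np.ones((4, 3))], [1.0, 1.0], delta=0.0
            )
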