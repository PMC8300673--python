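"""Unit and property tests for the closed-form Lyapunov inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jacrec as jr
from jacrec.exceptions import (
    DegenerateSystemError,
    DimensionError,
    UnderdeterminedWarning,
    UnstableSystemError,
    ValidationError,
)
from jacrec.fixtures import stable_sparse_jacobian
from jacrec.lyap_core import build_design, stack_constraints, unvec, vec


class TestVec:
    def test_column_stacking_order(self):
        x = np.array([[1.0, 3.0], [2.0, 4.0]])
        np.testing.assert_array_equal(vec(x), [1, 2, 3, 4])

    def test_identity(self):
        np.testing.assert_array_equal(vec(np.eye(2)), [1, 0, 0, 1])

    def test_unvec_inverts(self):
        np.testing.assert_array_equal(
            unvec(np.array([1.0, 2, 3, 4]), 2), [[1, 3], [2, 4]]
        )
        np.testing.assert_array_equal(unvec(np.zeros(9), 3), np.zeros((3, 3)))

    def test_round_trip_random(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 5))
        np.testing.assert_array_equal(unvec(vec(x), 5), x)
        v = rng.standard_normal(16)
        np.testing.assert_array_equal(vec(unvec(v, 4)), v)

    def test_dimension_errors(self):
        with pytest.raises(DimensionError):
            vec(np.zeros((2, 3)))
        with pytest.raises(DimensionError):
            unvec(np.zeros(5), 2)


class TestCommutationMatrix:
    def test_known_two_by_two(self):
        expected = [[1, 0, 0, 0], [0, 0, 1, 0], [0, 1, 0, 0], [0, 0, 0, 1]]
        np.testing.assert_array_equal(jr.commutation_matrix(2), expected)

    def test_trivial_one(self):
        np.testing.assert_array_equal(jr.commutation_matrix(1), [[1.0]])

    @pytest.mark.parametrize("n", range(1, 9))
    def test_transposes_and_self_inverse(self, n):
        c = jr.commutation_matrix(n)
        rng = np.random.default_rng(n)
        for _ in range(20 if n == 3 else 5):
            x = rng.standard_normal((n, n))
            np.testing.assert_array_equal(c @ vec(x), vec(x.T))
        np.testing.assert_array_equal(c @ c, np.eye(n * n))
        # permutation: exactly one 1 per row and column
        assert np.all(c.sum(axis=0) == 1) and np.all(c.sum(axis=1) == 1)

    def test_domain_error(self):
        with pytest.raises(DimensionError):
            jr.commutation_matrix(0)


class TestBuildDesign:
    def test_known_two_by_two_pattern(self):
        b = build_design(np.array([[2.0, 1.0], [1.0, 3.0]]))
        expected = [[4, 0, 2, 0], [1, 2, 3, 1], [1, 2, 3, 1], [0, 2, 0, 6]]
        np.testing.assert_allclose(b, expected)

    def test_identity_covariance_gives_i_plus_c(self):
        n = 3
        b = build_design(np.eye(n))
        np.testing.assert_allclose(b, np.eye(n * n) + jr.commutation_matrix(n))

    @pytest.mark.parametrize("n", [2, 3, 4, 6])
    def test_maps_vec_j_to_lyapunov_form(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            g = rng.standard_normal((n, n))
            g = g @ g.T + np.eye(n)
            j = rng.standard_normal((n, n))
            b = build_design(g)
            np.testing.assert_allclose(
                b @ vec(j), vec(j @ g + g @ j.T), rtol=0, atol=1e-12
            )

    def test_asymmetric_input_fails_hard(self):
        g = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValidationError):
            build_design(g)

    def test_mildly_asymmetric_input_warns_and_symmetrizes(self):
        g = np.array([[1.0, 0.5 + 1e-6], [0.5, 1.0]])
        with pytest.warns(jr.exceptions.AsymmetryWarning):
            b = build_design(g)
        gs = 0.5 * (g + g.T)
        j = np.arange(4.0).reshape(2, 2)
        np.testing.assert_allclose(b @ vec(j), vec(j @ gs + gs @ j.T))

    def test_middle_rows_identical_and_rank(self):
        """For N=2 the two centre rows coincide: rank is N(N+1)/2, not N^2."""
        rng = np.random.default_rng(7)
        for n in (2, 3, 4):
            g = rng.standard_normal((n, n))
            g = g @ g.T + np.eye(n)
            b = build_design(g)
            assert np.linalg.matrix_rank(b) == n * (n + 1) // 2
        b2 = build_design(np.array([[2.0, 1.0], [1.0, 3.0]]))
        np.testing.assert_array_equal(b2[1], b2[2])


class TestStackConstraints:
    def test_single_constraint_row_augments_system(self):
        g = np.array([[2.0, 1.0], [1.0, 3.0]])
        b = build_design(g)
        d = -2.0 * vec(np.eye(2))
        system = stack_constraints(b, d, jr.ZeroPattern([(0, 1)], 2))
        assert system.design.shape == (5, 4)
        # J12 sits at vec position 2 (column-stacking)
        np.testing.assert_array_equal(system.design[4], [0, 0, 1, 0])
        np.testing.assert_array_equal(system.rhs[4:], [0.0])
        np.testing.assert_array_equal(system.rhs[:4], d)

    def test_empty_pattern_leaves_design_unchanged(self):
        g = np.eye(3)
        b = build_design(g)
        system = stack_constraints(b, np.zeros(9), jr.ZeroPattern([], 3))
        np.testing.assert_array_equal(system.design, b)

    def test_full_pattern_is_permuted_identity(self):
        n = 2
        pattern = jr.ZeroPattern([(i, j) for i in range(n) for j in range(n)], n)
        system = stack_constraints(
            build_design(np.eye(n)), np.zeros(n * n), pattern
        )
        block = system.design[n * n :]
        assert block.shape == (n * n, n * n)
        assert np.all(block.sum(axis=0) == 1) and np.all(block.sum(axis=1) == 1)

    def test_invalid_pattern_entries_rejected(self):
        with pytest.raises(ValidationError):
            jr.ZeroPattern([(0, 1), (0, 1)], 2)
        with pytest.raises(ValidationError):
            jr.ZeroPattern([(2, 0)], 2)


class TestSolveReconstruction:
    def test_exact_determined_system(self):
        """A consistent full-rank stack is solved exactly with zero residual."""
        g = np.array([[2.0, 1.0], [1.0, 3.0]])
        j_true = np.array([[-1.0, 0.0], [0.2, -2.0]])  # true zero at (0, 1)
        rhs = vec(j_true @ g + g @ j_true.T)
        system = stack_constraints(
            build_design(g), rhs, jr.ZeroPattern([(0, 1)], 2)
        )
        sol = jr.solve_reconstruction(system)
        assert sol.residual_norm < 1e-12
        assert not sol.rank_deficient
        np.testing.assert_allclose(sol.j, vec(j_true), atol=1e-12)

    def test_worked_two_variable_case(self):
        """Triangular 2-variable system: the oracle covariance determines J."""
        j_true = np.array([[-1.0, 0.0], [0.5, -2.0]])
        gamma = jr.forward_lyapunov(j_true, np.eye(2))
        np.testing.assert_allclose(
            gamma, [[1.0, 1 / 6], [1 / 6, 13 / 24]], atol=1e-12
        )
        res = jr.reconstruct_jacobian(gamma, np.eye(2), jr.ZeroPattern([(0, 1)], 2))
        np.testing.assert_allclose(res.jacobian, j_true, atol=1e-10)

    def test_overdetermined_matches_normal_equations(self):
        rng = np.random.default_rng(11)
        g = rng.standard_normal((3, 3))
        g = g @ g.T + np.eye(3)
        b = build_design(g)
        d = rng.standard_normal(9)  # inconsistent rhs
        pattern = jr.ZeroPattern([(0, 1), (1, 0), (0, 2), (2, 0)], 3)
        system = stack_constraints(b, d, pattern)
        sol = jr.solve_reconstruction(system)
        bh, dh = system.design, system.rhs
        expected = np.linalg.solve(bh.T @ bh, bh.T @ dh)
        np.testing.assert_allclose(sol.j, expected, rtol=1e-8, atol=1e-10)

    def test_all_zero_design_is_degenerate(self):
        system = jr.DesignSystem(
            np.zeros((4, 4)), np.zeros(4), 2, jr.ZeroPattern([], 2)
        )
        with pytest.raises(DegenerateSystemError):
            jr.solve_reconstruction(system)


class TestForwardLyapunov:
    def test_negative_identity(self):
        np.testing.assert_allclose(
            jr.forward_lyapunov(-np.eye(2), np.eye(2)), np.eye(2)
        )

    def test_diagonal_closed_form(self):
        j = np.diag([-1.0, -2.0])
        np.testing.assert_allclose(
            jr.forward_lyapunov(j, np.eye(2)), np.diag([1.0, 0.5])
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_residual_and_psd(self, seed):
        j, _ = stable_sparse_jacobian(8, seed=seed)
        d = np.diag(np.random.default_rng(seed).uniform(0.5, 2.0, 8))
        g = jr.forward_lyapunov(j, d)
        resid = np.linalg.norm(j @ g + g @ j.T + 2 * d)
        assert resid <= 1e-10 * np.linalg.norm(d)
        assert np.all(np.linalg.eigvalsh(g) > 0)

    def test_unstable_rejected(self):
        with pytest.raises(UnstableSystemError):
            jr.forward_lyapunov(np.array([[0.1]]), np.eye(1))


class TestSpectrum:
    def test_real_leading(self):
        s = jr.spectrum(np.diag([-1.0, -3.0]))
        assert s.leading == -1.0 and s.tag == "real"

    def test_rotation_gives_complex_pair_nonneg_imag_first(self):
        s = jr.spectrum(np.array([[0.0, -1.0], [1.0, 0.0]]))
        assert s.tag == "complex-pair"
        assert s.leading == pytest.approx(1j)
        assert s.eigenvalues[0].imag > 0  # +i before -i

    def test_matches_characteristic_roots(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            j = rng.standard_normal((3, 3))
            got = jr.spectrum(j).eigenvalues
            want = np.roots(np.poly(j))
            got_s = np.sort_complex(got)
            want_s = np.sort_complex(want)
            np.testing.assert_allclose(got_s, want_s, atol=1e-10)

    def test_descending_real_part(self):
        ev = jr.spectrum(np.diag([-3.0, -1.0, -2.0])).eigenvalues
        assert list(ev.real) == [-1.0, -2.0, -3.0]


class TestReconstructJacobian:
    def test_diagonal_system_recovered_exactly(self):
        j = -np.diag([1.0, 2.0, 3.0])
        gamma = jr.forward_lyapunov(j, np.eye(3))
        np.testing.assert_allclose(gamma, np.diag([1.0, 0.5, 1 / 3]), atol=1e-14)
        pattern = jr.ZeroPattern(
            [(i, k) for i in range(3) for k in range(3) if i != k], 3
        )
        res = jr.reconstruct_jacobian(gamma, np.eye(3), pattern)
        np.testing.assert_allclose(res.jacobian, j, atol=1e-10)

    @pytest.mark.parametrize("n", [4, 6, 12])
    def test_oracle_round_trip(self, n):
        for seed in range(3):
            j_true, pattern = stable_sparse_jacobian(n, seed=seed)
            gamma = jr.forward_lyapunov(j_true, np.eye(n))
            res = jr.reconstruct_jacobian(gamma, np.eye(n), pattern)
            assert np.abs(res.jacobian - j_true).max() < 1e-8
            assert res.zeros_enforced
            assert len(res.eigenvalues) == n

    def test_structured_and_dense_solvers_agree(self):
        j_true, pattern = stable_sparse_jacobian(12, seed=4)
        gamma = jr.forward_lyapunov(j_true, np.eye(12))
        a = jr.reconstruct_jacobian(gamma, np.eye(12), pattern, solver="lstsq")
        b = jr.reconstruct_jacobian(gamma, np.eye(12), pattern, solver="normal")
        np.testing.assert_allclose(a.jacobian, b.jacobian, atol=1e-9)

    def test_enforced_zeros_are_exact(self, metacommunity_pattern):
        rng = np.random.default_rng(0)
        n = metacommunity_pattern.dimension
        g = rng.standard_normal((n, n))
        g = g @ g.T + n * np.eye(n)
        res = jr.reconstruct_jacobian(g, np.eye(n), metacommunity_pattern)
        for i, j in metacommunity_pattern:
            assert res.jacobian[i, j] == 0.0

    def test_underdetermined_warns_and_flags(self):
        j = -np.eye(3)
        gamma = jr.forward_lyapunov(j, np.eye(3))
        small = jr.ZeroPattern([(0, 1)], 3)
        with pytest.warns(UnderdeterminedWarning):
            res = jr.reconstruct_jacobian(gamma, np.eye(3), small)
        assert res.underdetermined and res.rank_deficient

    def test_zero_covariance_degenerate(self):
        with pytest.raises(DegenerateSystemError):
            jr.reconstruct_jacobian(
                np.zeros((2, 2)), np.eye(2), jr.ZeroPattern([(0, 1)], 2)
            )

    def test_linearity_in_noise_amplitude(self):
        """Scaling D at fixed covariance scales the reconstructed J linearly."""
        j_true, pattern = stable_sparse_jacobian(6, seed=2)
        gamma = jr.forward_lyapunov(j_true, np.eye(6))
        base = jr.reconstruct_jacobian(gamma, np.eye(6), pattern)
        scaled = jr.reconstruct_jacobian(gamma, 3.5 * np.eye(6), pattern)
        np.testing.assert_allclose(scaled.jacobian, 3.5 * base.jacobian, atol=1e-9)

    def test_permutation_equivariance(self):
        j_true, pattern = stable_sparse_jacobian(6, seed=8)
        d = np.diag(np.linspace(0.5, 2.0, 6))
        gamma = jr.forward_lyapunov(j_true, d)
        perm = [3, 0, 5, 1, 4, 2]
        p = np.zeros((6, 6))
        p[perm, np.arange(6)] = 1.0
        res = jr.reconstruct_jacobian(gamma, d, pattern)
        res_p = jr.reconstruct_jacobian(
            p @ gamma @ p.T, p @ d @ p.T, pattern.permuted(perm)
        )
        np.testing.assert_allclose(res_p.jacobian, p @ res.jacobian @ p.T, atol=1e-8)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=5),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_design_consistency_property(n, seed):
    """B @ vec(J) equals vec(J G + G J.T) for random symmetric PD G and any J."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, n))
    g = g @ g.T + np.eye(n)
    j = rng.standard_normal((n, n))
    np.testing.assert_allclose(
        build_design(g) @ vec(j), vec(j @ g + g @ j.T), atol=1e-10
    )
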