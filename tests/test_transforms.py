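"""Quasimonomial transforms, kernel decoupling, LV embedding, SVD diagnostics."""

import numpy as np
import pytest

from canred import (
    GLVModel,
    ModelError,
    QuasimonomialTransform,
    apply_quasimonomial,
    ba_decomposition,
    evaluate_rhs,
    jacobian,
    kernel_decoupling,
    log_modes,
    lv_embedding,
    make_toy_model,
    normalize,
    simulate,
    svd_analysis,
)
from canred.transforms import modal_decomposition

from conftest import random_glv

# independently computed with numpy.linalg on the toy kinetic matrix
TOY_SLOW_VECTOR = np.array([0.93914251, 0.28155498, 0.19682006])
TOY_LAMHAT = np.array([-0.04977865, -0.99406543, -1.41751755])


class TestQuasimonomial:
    def test_identity_leaves_model_unchanged(self, toy_glv):
        out = apply_quasimonomial(toy_glv, QuasimonomialTransform(np.eye(3)))
        np.testing.assert_allclose(out.lam, toy_glv.lam)
        np.testing.assert_allclose(out.A, toy_glv.A)
        np.testing.assert_allclose(out.B, toy_glv.B)

    def test_toy_transform_by_slow_basis(self, toy_glv):
        """C = V_B turns the slow singular direction into an explicit variable."""
        rep = svd_analysis(toy_glv.B)
        out = apply_quasimonomial(toy_glv, QuasimonomialTransform(rep.V))
        np.testing.assert_allclose(out.lam, TOY_LAMHAT, atol=1e-6)
        np.testing.assert_allclose(np.abs(out.lam), [0.05, 0.99, 1.42], atol=0.005)
        np.testing.assert_allclose(out.A[2], TOY_SLOW_VECTOR, atol=1e-6)
        # the slow variable has negligible exponents everywhere
        assert np.max(np.abs(out.B[:, 2])) < 1e-3

    def test_round_trip(self, rng, toy_glv):
        C = rng.uniform(-1, 1, (3, 3)) + 2 * np.eye(3)
        t = QuasimonomialTransform(C)
        back = apply_quasimonomial(apply_quasimonomial(toy_glv, t), t.inverse())
        np.testing.assert_allclose(back.lam, toy_glv.lam, atol=1e-10)
        np.testing.assert_allclose(back.A, toy_glv.A, atol=1e-10)
        np.testing.assert_allclose(back.B, toy_glv.B, atol=1e-10)

    def test_singular_transform_rejected(self):
        with pytest.raises(ModelError, match="condition"):
            QuasimonomialTransform(np.ones((2, 2)))

    def test_trajectories_map_between_coordinate_systems(self, rng):
        """x(t) = y(t)^C along solutions of the transformed system."""
        glv = random_glv(rng, 3, 2, steady_state=np.array([1.0, 1.2, 0.8]))
        C = rng.uniform(-0.5, 0.5, (3, 3)) + np.eye(3)
        t = QuasimonomialTransform(C)
        out = apply_quasimonomial(glv, t)
        x0 = np.array([1.1, 0.9, 1.05])
        tx = simulate(glv, x0, 1.0, n_points=20)
        ty = simulate(out, t.map_state(x0), 1.0, n_points=20)
        mapped = np.array([t.unmap_state(y) for y in ty.states])
        np.testing.assert_allclose(mapped, tx.states, rtol=1e-6, atol=1e-8)

    def test_eigenvalue_invariance_across_equivalence_class(self, rng):
        """Jacobian spectra at corresponding steady states coincide."""
        for _ in range(50):
            xs = rng.uniform(0.5, 2.0, 3)
            glv = random_glv(rng, 3, 3, steady_state=xs)
            C = rng.uniform(-0.5, 0.5, (3, 3)) + np.eye(3)
            t = QuasimonomialTransform(C)
            out = apply_quasimonomial(glv, t)
            w1 = np.sort_complex(np.linalg.eigvals(jacobian(glv, xs)))
            w2 = np.sort_complex(np.linalg.eigvals(jacobian(out, t.map_state(xs))))
            np.testing.assert_allclose(w1, w2, atol=1e-8)


class TestKernelDecoupling:
    def test_rank_deficient_exponent_matrix(self):
        glv = GLVModel(lam=[-0.1, -0.1, -0.1],
                       A=[[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]],
                       B=[[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        out, decoupled = kernel_decoupling(glv)
        assert decoupled == [2]
        np.testing.assert_allclose(np.abs(out.B), [[1, 0, 0], [0, 1, 0]], atol=1e-12)

    def test_full_rank_nothing_to_decouple(self, toy_glv):
        out, decoupled = kernel_decoupling(toy_glv)
        assert decoupled == []
        assert out is toy_glv

    def test_two_dimensional_kernel_gives_two_zero_columns(self):
        B = np.array([[1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0]])
        glv = GLVModel(lam=np.full(4, -0.1), A=np.ones((4, 2)) * 0.2, B=B)
        out, decoupled = kernel_decoupling(glv)
        assert len(decoupled) == 2
        assert np.all(out.B[:, decoupled] == 0.0)
        # rank preserved on the coupled part
        assert np.linalg.matrix_rank(out.B) == 2

    def test_decoupled_variable_does_not_influence_others(self):
        """Integrating with two values of a decoupled variable leaves the
        remaining coordinates identical (de facto uncoupled dynamics)."""
        glv = GLVModel(lam=[-0.2, -0.3, -0.1],
                       A=[[0.1, -0.2], [-0.3, 0.1], [0.2, 0.1]],
                       B=[[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        out, decoupled = kernel_decoupling(glv)
        j = decoupled[0]
        y0 = np.array([1.2, 0.9, 1.0])
        ya = y0.copy()
        yb = y0.copy()
        yb[j] = 3.7
        ta = simulate(out, ya, 2.0, n_points=15)
        tb = simulate(out, yb, 2.0, n_points=15)
        keep = [i for i in range(3) if i != j]
        np.testing.assert_allclose(ta.states[:, keep], tb.states[:, keep],
                                   rtol=1e-7, atol=1e-9)


class TestLVEmbedding:
    def test_toy_interaction_matrix_is_kinetic_matrix(self, toy_glv):
        lvm = lv_embedding(toy_glv)
        np.testing.assert_allclose(lvm.M, toy_glv.B)
        np.testing.assert_allclose(lvm.bias, toy_glv.B @ np.array([-1.0, -1.0, -1.0]))

    def test_lotka_volterra_input_unchanged(self, rng):
        A = rng.uniform(-1, 1, (3, 3))
        glv = GLVModel(lam=rng.uniform(-1, 0, 3), A=A, B=np.eye(3))
        lvm = lv_embedding(glv)
        np.testing.assert_allclose(lvm.M, A)

    def test_equivalence_class_maps_to_same_canonical_form(self, rng):
        glv = random_glv(rng, 3, 4)
        C = rng.uniform(-0.5, 0.5, (3, 3)) + np.eye(3)
        out = apply_quasimonomial(glv, QuasimonomialTransform(C))
        lv1 = lv_embedding(glv)
        lv2 = lv_embedding(out)
        np.testing.assert_allclose(lv1.M, lv2.M, atol=1e-10)
        np.testing.assert_allclose(lv1.bias, lv2.bias, atol=1e-10)


class TestSVDAnalysis:
    def test_toy_slow_vector(self, toy_glv):
        rep = svd_analysis(toy_glv.B)
        np.testing.assert_allclose(rep.slow_vector, TOY_SLOW_VECTOR, atol=1e-6)
        np.testing.assert_allclose(rep.slow_vector, [0.939, 0.281, 0.197],
                                   atol=1e-3)

    def test_identity_matrix(self):
        rep = svd_analysis(np.eye(4))
        np.testing.assert_allclose(rep.S, np.ones(4))
        assert rep.effective_rank == 4

    def test_reconstruction_and_gram_eigenvalues(self, rng):
        A = rng.normal(size=(5, 3))
        rep = svd_analysis(A)
        np.testing.assert_allclose(rep.U @ np.diag(rep.S) @ rep.V.T, A, atol=1e-10)
        gram = np.sort(np.linalg.eigvalsh(A.T @ A))[::-1]
        np.testing.assert_allclose(rep.S**2, gram, atol=1e-10)
        assert np.all(np.diff(rep.S) <= 0)
        # orthonormality
        np.testing.assert_allclose(rep.V.T @ rep.V, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(rep.U.T @ rep.U, np.eye(3), atol=1e-10)

    def test_sign_convention(self, rng):
        rep = svd_analysis(rng.normal(size=(4, 4)))
        for j in range(4):
            col = rep.V[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestBADecomposition:
    def test_toy_is_kinetically_dominated(self, toy_glv):
        dec = ba_decomposition(toy_glv)
        np.testing.assert_allclose(dec.S_A, np.ones(3))
        assert dec.dominance == "kinetic"

    def test_stoichiometric_dominance_constructed(self):
        # B with orthonormal rows (spread 1), A ill conditioned (spread 1e4)
        B = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        A = np.array([[100.0, 0.0], [0.0, 0.01], [0.0, 0.0]])
        glv = GLVModel(lam=np.zeros(3) - 0.1, A=A, B=B)
        dec = ba_decomposition(glv)
        assert dec.dominance == "stoichiometric"
        assert dec.sa_range[1] / dec.sa_range[0] == pytest.approx(1e4)

    def test_reconstruction_random(self, rng):
        glv = random_glv(rng, 4, 6)
        dec = ba_decomposition(glv)
        np.testing.assert_allclose(dec.reconstruct(), glv.B @ glv.A, atol=1e-10)
        W = dec.W
        np.testing.assert_allclose(W @ W.T, np.eye(W.shape[0]), atol=1e-10)


class TestLogModes:
    def test_toy_slow_direction_close_to_singular_vector(self, toy):
        nz = normalize(toy)
        basis = log_modes(nz, np.ones(3))
        rel = np.abs(basis.slow_direction - TOY_SLOW_VECTOR) / TOY_SLOW_VECTOR
        assert np.max(rel) < 0.005

    def test_diagonal_jacobian_modes_are_axes(self):
        basis = modal_decomposition(np.diag([-1.0, -100.0]))
        np.testing.assert_allclose(basis.slow_direction, [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(np.sort(basis.eigenvalues.real), [-100.0, -1.0])

    def test_block_diagonalization_random_stable(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 6))
            J = rng.normal(size=(n, n)) - (n + 1) * np.eye(n)
            basis = modal_decomposition(J)
            Minv = np.linalg.inv(basis.M)
            T = basis.M @ J @ Minv
            mask = np.ones((n, n), dtype=bool)
            for idx, _ in basis.block_structure:
                for a in idx:
                    for b in idx:
                        mask[a, b] = False
            if mask.any():
                assert np.max(np.abs(T[mask])) < 1e-8 * max(1.0, np.abs(J).max())

    def test_complex_pairs_kept_as_rotation_blocks(self):
        J = np.array([[-1.0, 2.0], [-2.0, -1.0]])  # eigenvalues -1 +/- 2i
        basis = modal_decomposition(J)
        (idx, lam), = [b for b in basis.block_structure if len(b[0]) == 2]
        assert lam == pytest.approx(-1 + 2j)
        T = basis.M @ J @ np.linalg.inv(basis.M)
        np.testing.assert_allclose(T, [[-1.0, 2.0], [-2.0, -1.0]], atol=1e-10)

    def test_nonhyperbolic_warns(self):
        with pytest.warns(UserWarning, match="non-hyperbolic"):
            basis = modal_decomposition(np.diag([0.0, -1.0]))
        assert basis.warnings
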