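"""Element blocks, static condensation, global assembly and its invariants."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

import monofem.ionic as ionic
from monofem.assembly import (Conductivity, ElementBlocks, SystemOperators,
                              assemble_system, condense, element_blocks,
                              solve_steady)
from monofem.elements import CORNER_SIGNS, gauss_rule, map_element
from monofem.mesh import build_box_mesh
from monofem.time_integration import FullImplicitOperators, si_step

D_ISO = Conductivity.isotropic(0.0952)


def unit_cube_mapped(h=1.0, k=2):
    return map_element(0.5 * h * (CORNER_SIGNS + 1.0), gauss_rule(k))


class TestConductivity:
    def test_tensor_eigenvalues(self):
        D = Conductivity(d_l=0.0952, d_t=0.0126, fiber=(1, 0, 0))
        np.testing.assert_allclose(sorted(np.linalg.eigvalsh(D.tensor())),
                                   [0.0126, 0.0126, 0.0952])

    def test_rejects_bad_ordering(self):
        with pytest.raises(ValueError):
            Conductivity(d_l=0.01, d_t=0.02)


class TestElementBlocks:
    def test_q1_has_no_nc_blocks(self):
        blocks = element_blocks(unit_cube_mapped(), D_ISO, 0.01, "Q1")
        assert blocks.L.shape == (0, 8)
        assert blocks.K_alpha.shape == (0, 0)
        np.testing.assert_allclose(blocks.K_u, blocks.K_u.T, atol=1e-14)

    def test_q1nc_blocks_symmetric_spd(self):
        blocks = element_blocks(unit_cube_mapped(), D_ISO, 0.01, "Q1NC")
        np.testing.assert_allclose(blocks.K_alpha, blocks.K_alpha.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(blocks.K_alpha) > 0)
        assert np.all(np.linalg.eigvalsh(blocks.K_u) > 0)

    def test_q1nc_blocks_match_symbolic_integration(self):
        # independent oracle: symbolic integrals of the printed polynomials
        # on an axis-aligned cube of side h (map xi -> h/2 * (xi+1)).
        # The 2x2x2 rule is exact for every term of degree <= 3 per axis:
        # the whole L block and the stiffness part of K_alpha.
        import sympy as sp
        h, dt, d = 2.0, 0.05, 0.0952
        x = sp.symbols("x1 x2 x3")
        W = [1 - x[0] ** 2, 1 - x[1] ** 2, 1 - x[2] ** 2]
        N = [sp.Rational(1, 8) * (1 + int(s[0]) * x[0]) * (1 + int(s[1]) * x[1])
             * (1 + int(s[2]) * x[2]) for s in CORNER_SIGNS]
        jac = h / 2

        def integral(expr):
            return float(sp.integrate(expr, (x[0], -1, 1), (x[1], -1, 1),
                                      (x[2], -1, 1))) * jac ** 3

        K_alpha_exact = np.zeros((3, 3))
        L_exact = np.zeros((3, 8))
        for c in range(3):
            for e in range(3):
                grad = sum(sp.diff(W[c], v) * sp.diff(W[e], v) for v in x) / jac ** 2
                K_alpha_exact[c, e] = integral(d * grad)
            for b in range(8):
                grad = sum(sp.diff(W[c], v) * sp.diff(N[b], v) for v in x) / jac ** 2
                L_exact[c, b] = integral(W[c] * N[b] / dt + d * grad)
        stiff = element_blocks(unit_cube_mapped(h), D_ISO, None, "Q1NC")
        np.testing.assert_allclose(stiff.K_alpha, K_alpha_exact, rtol=1e-12, atol=1e-14)
        full = element_blocks(unit_cube_mapped(h), D_ISO, dt, "Q1NC")
        np.testing.assert_allclose(full.L, L_exact, rtol=1e-12, atol=1e-13)

    def test_pure_stiffness_annihilates_constants(self):
        blocks = element_blocks(unit_cube_mapped(), Conductivity.isotropic(1.0),
                                None, "Q1")
        np.testing.assert_allclose(blocks.K_u @ np.ones(8), 0.0, atol=1e-13)


class TestCondense:
    def test_zero_coupling_returns_K_u(self):
        blocks = ElementBlocks(K_u=np.diag([2.0, 3.0]), L=np.zeros((1, 2)),
                               K_alpha=np.array([[4.0]]))
        np.testing.assert_allclose(condense(blocks), np.diag([2.0, 3.0]))

    def test_toy_schur_complement(self):
        blocks = ElementBlocks(K_u=np.array([[2.0, 0.0], [0.0, 2.0]]),
                               L=np.array([[1.0, 0.0]]),
                               K_alpha=np.array([[2.0]]))
        np.testing.assert_allclose(condense(blocks), [[1.5, 0.0], [0.0, 2.0]])

    def test_reduces_quadratic_form(self, rng):
        blocks = element_blocks(unit_cube_mapped(), D_ISO, 0.01, "Q1NC")
        A_e = condense(blocks)
        np.testing.assert_allclose(A_e, A_e.T, atol=1e-12)
        for _ in range(10):
            x = rng.standard_normal(8)
            assert x @ A_e @ x <= x @ blocks.K_u @ x + 1e-12

    def test_singular_K_alpha_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            ElementBlocks(K_u=np.eye(2), L=np.ones((1, 2)),
                          K_alpha=np.zeros((1, 1)))


class TestGlobalAssembly:
    def test_single_element_matches_element_matrix(self):
        mesh = build_box_mesh((1, 1, 1), 1.0, "Q1NC")
        ops = assemble_system(mesh, D_ISO, 0.01, "Q1NC")
        blocks = element_blocks(unit_cube_mapped(), D_ISO, 0.01, "Q1NC")
        np.testing.assert_allclose(ops.A.toarray()[np.ix_(mesh.elems[0], mesh.elems[0])],
                                   condense(blocks), rtol=1e-12)

    def test_two_element_sparsity(self):
        mesh = build_box_mesh((2, 1, 1), 1.0, "Q1")
        ops = assemble_system(mesh, D_ISO, 0.01, "Q1")
        A = ops.A.toarray()
        shared = np.intersect1d(mesh.elems[0], mesh.elems[1])
        assert len(shared) == 4
        only0 = np.setdiff1d(mesh.elems[0], shared)
        only1 = np.setdiff1d(mesh.elems[1], shared)
        assert np.all(A[np.ix_(only0, only1)] == 0)

    def test_stiffness_nullspace_is_constant(self):
        mesh = build_box_mesh((3, 2, 1), 0.8, "Q1NC")
        ops = SystemOperators(mesh, D_ISO, dt=None, family="Q1NC")
        np.testing.assert_allclose(ops.A @ np.ones(mesh.n_nodes), 0.0, atol=1e-11)


class TestElementRhs:
    def setup_ops(self, family="Q1"):
        mesh = build_box_mesh((1, 1, 1), 1.0, family)
        return assemble_system(mesh, D_ISO, 0.01, family)

    def test_rest_state_gives_zero(self):
        ops = self.setup_ops("Q1NC")
        react = np.zeros((1, 8))
        p_u, p_a = ops.element_rhs(react)
        np.testing.assert_allclose(p_u, 0.0)
        np.testing.assert_allclose(p_a, 0.0)
        b, _ = ops.assemble_rhs(react)
        u_new = ops.lu.solve(-b)
        np.testing.assert_allclose(u_new, 0.0, atol=1e-15)

    def test_uniform_mass_action(self):
        ops = self.setup_ops()
        phi_bar, dt = 0.37, 0.01
        react = np.full((1, 8), phi_bar / dt)
        p_u, _ = ops.element_rhs(react)
        np.testing.assert_allclose(p_u, phi_bar / dt / 8.0, rtol=1e-13)

    def test_constant_stimulus_load(self):
        ops = self.setup_ops()
        react = np.full((1, 8), 0.2)
        p_u, _ = ops.element_rhs(react)
        np.testing.assert_allclose(p_u, 0.2 / 8.0, rtol=1e-13)  # 0.2 * vol / 8


def one_monolithic_si_step(mesh, family, D, dt, state, params):
    """Oracle: one SI step keeping all alpha as explicit unknowns."""
    fi = FullImplicitOperators(mesh, D, dt, family)
    ops = fi.ops
    phi = ops.interpolate_qp(state.u, state.alpha)
    react = phi / dt + ionic.ionic_current(phi, state.r, params)
    integ = react * ops.wdet
    p_e = np.einsum("qa,eq->ea", fi.B, integ)
    p = np.bincount(fi.dofmap.ravel(), weights=p_e.ravel(), minlength=fi.ndof)
    z = spla.spsolve(fi.J0, p)
    return fi._split(z)


class TestCondensationEquivalence:
    @pytest.mark.parametrize("dims,h", [((2, 1, 1), 1.0), ((3, 3, 3), 1.0)])
    def test_si_step_matches_monolithic(self, dims, h, rng):
        mesh = build_box_mesh(dims, h, "Q1NC")
        params = ionic.MODIFIED_AP_PARAMS
        dt = 0.01
        ops = assemble_system(mesh, D_ISO, dt, "Q1NC")
        state = ops.initial_state(params)
        x = mesh.nodes
        state.u = 0.5 + 0.3 * np.sin(x[:, 0]) * np.cos(0.5 * x[:, 1]) + 0.1 * x[:, 2]
        state.alpha = 0.05 * rng.standard_normal(state.alpha.shape)
        state.r = 0.1146 + 0.02 * rng.standard_normal(state.r.shape)
        new = si_step(state, ops, params)
        u_mono, a_mono = one_monolithic_si_step(mesh, "Q1NC", D_ISO, dt, state, params)
        np.testing.assert_allclose(new.u, u_mono, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(new.alpha, a_mono, rtol=1e-9, atol=1e-11)

    def test_recovered_alpha_zeroes_internal_residual(self, rng):
        # substituting u_{n+1}, alpha_{n+1} into the internal-mode equation
        # L u + K_alpha a - p_alpha = 0 must give a tiny residual
        mesh = build_box_mesh((2, 2, 1), 1.0, "Q1NC")
        params = ionic.MODIFIED_AP_PARAMS
        ops = assemble_system(mesh, D_ISO, 0.01, "Q1NC")
        state = ops.initial_state(params)
        state.u = rng.uniform(0, 1, mesh.n_nodes)
        phi = ops.interpolate_qp(state.u, state.alpha)
        react = phi / ops.dt + ionic.ionic_current(phi, state.r, params)
        b, p_alpha = ops.assemble_rhs(react)
        u_new = ops.lu.solve(-b)
        a_new = ops.recover_alpha(u_new, p_alpha)
        res = (np.einsum("ecb,eb->ec", ops.L, u_new[mesh.elems])
               + np.einsum("ecd,ed->ec", ops.K_alpha, a_new) - p_alpha)
        assert np.abs(res).max() < 1e-10 * max(1.0, np.abs(p_alpha).max())


class TestQ1ncReduction:
    def test_alpha_zero_reproduces_q1_bitwise(self, rng):
        """Constraining alpha == 0 must reproduce the Q1 trajectory exactly."""
        mesh = build_box_mesh((3, 1, 1), 1.0, "Q1")
        params = ionic.MODIFIED_AP_PARAMS
        dt = 0.01
        ops_q1 = assemble_system(mesh, D_ISO, dt, "Q1")
        ops_nc = assemble_system(mesh, D_ISO, dt, "Q1NC")
        # impose the constraint: zero coupling, zero recovery, Q1 solve
        ops_nc.L[:] = 0.0
        ops_nc.K_alpha_inv[:] = 0.0
        ops_nc.K_alpha_inv_L[:] = 0.0
        ops_nc.A = ops_q1.A
        ops_nc.lu = ops_q1.lu
        u0 = rng.uniform(0, 0.4, mesh.n_nodes)
        s_q1 = ops_q1.initial_state(params)
        s_nc = ops_nc.initial_state(params)
        s_q1.u = u0.copy()
        s_nc.u = u0.copy()
        for _ in range(5):
            s_q1 = si_step(s_q1, ops_q1, params)
            s_nc = si_step(s_nc, ops_nc, params)
        assert np.array_equal(s_q1.u, s_nc.u)
        assert np.all(s_nc.alpha == 0.0)
        assert np.array_equal(s_q1.r, s_nc.r)


class TestConservation:
    @pytest.mark.parametrize("family", ["Q1", "Q1NC"])
    def test_mass_conserved_without_reaction(self, family, rng):
        # f == 0 via c1 = c2 = 0; zero-flux boundaries; no stimulus
        mesh = build_box_mesh((4, 2, 1), 0.9, family)
        params = ionic.IonicParams(c1=0.0, c2=0.0)
        ops = assemble_system(mesh, Conductivity.isotropic(0.05), 0.05, family)
        state = ops.initial_state(params)
        state.u = rng.uniform(0, 1, mesh.n_nodes)
        mass_u = ops.element_rhs(np.ones(ops.wdet.shape))[0] * 1.0  # int N_a dx
        w_mass = np.bincount(mesh.elems.ravel(), weights=mass_u.ravel(),
                             minlength=mesh.n_nodes)
        w_alpha = np.einsum("eq,qc->ec", ops.wdet, ops.W)            # int W_c dx

        def total(s):
            return w_mass @ s.u + float(np.sum(w_alpha * s.alpha))

        m0 = total(state)
        for _ in range(100):
            state = si_step(state, ops, params)
        assert abs(total(state) - m0) < 1e-10 * abs(m0)


class TestPatchReproduction:
    @pytest.mark.parametrize("family", ["Q1", "Q2", "Q1NC"])
    def test_linear_field_reproduced_exactly(self, family):
        # steady diffusion with linear exact solution via Dirichlet faces
        mesh = build_box_mesh((2, 1.5, 1), 0.6, family)  # has remainder layers
        exact = lambda p: 1.0 + 2.0 * p[:, 0] - 3.0 * p[:, 1] + 0.5 * p[:, 2]
        boundary = np.unique(np.concatenate(
            [mesh.node_sets[n] for n in ("xmin", "xmax", "ymin", "ymax", "zmin", "zmax")]))
        D = Conductivity(d_l=0.0952, d_t=0.0126, fiber=(1, 0, 0))
        u = solve_steady(mesh, D, boundary, exact(mesh.nodes[boundary]), family)
        np.testing.assert_allclose(u, exact(mesh.nodes), rtol=1e-9, atol=1e-10)
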