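"""Mesh generation, FE machinery and the staggered incremental solver."""

import warnings

import numpy as np
import pytest

from arterysim import fem_solver as fem
from arterysim import material as mat
from arterysim import mesh as msh
from arterysim import tensors as tn

warnings.filterwarnings("ignore", category=RuntimeWarning)

UNIT_CUBE = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)
ONE_HEX = np.array([[0, 1, 2, 3, 4, 5, 6, 7]])


class TestMesh:
    def test_s_test_geometry_valid(self):
        m = msh.build_cylinder_mesh(1.2, 0.19, 0.125, 7.8,
                                    n_circ=16, n_axial=10)
        _, detJ, _ = fem.shape_gradients_at_gauss(m.nodes, m.elements)
        assert np.all(detJ > 0)
        inner = fem.facet_areas(m.nodes, m.inner_facets).sum()
        outer = fem.facet_areas(m.nodes, m.outer_facets).sum()
        assert inner == pytest.approx(2 * np.pi * m.r_inner * 7.8, rel=0.02)
        assert outer == pytest.approx(2 * np.pi * 1.2 * 7.8, rel=0.02)

    def test_coarse_override_still_valid(self):
        m = msh.build_cylinder_mesh(1.2, 0.19, 0.125, 7.8, n_circ=4,
                                    n_axial=2, n_rad_media=1, n_rad_adv=1)
        _, detJ, _ = fem.shape_gradients_at_gauss(m.nodes, m.elements)
        assert np.all(detJ > 0)

    def test_layer_interface_radius(self):
        m = msh.build_cylinder_mesh(1.2, 0.19, 0.125, 7.8, n_circ=8, n_axial=4)
        assert m.r_interface == pytest.approx(1.2 - 0.19 + 0.125)
        # mean nodal radius per element (centroids of curved facets sag inward)
        r_nodes = np.hypot(m.nodes[:, 0], m.nodes[:, 1])[m.elements].mean(axis=1)
        assert np.all(r_nodes[m.layer == 0] < m.r_interface)
        assert np.all(r_nodes[m.layer == 1] > m.r_interface)

    def test_default_resolution_minimum_layers(self):
        m = msh.build_cylinder_mesh(1.2, 0.19, 0.125, 7.8, n_circ=8, n_axial=4)
        n_rm, n_ra, _, _ = m.divisions
        assert n_rm >= 3 and n_ra >= 2

    def test_rejects_degenerate_geometry(self):
        with pytest.raises(ValueError):
            msh.build_cylinder_mesh(1.2, -0.1, 0.05, 7.8)
        with pytest.raises(ValueError):
            msh.build_cylinder_mesh(1.2, 0.19, 0.25, 7.8)


class TestElementMachinery:
    def test_patch_uniaxial_displacement(self):
        # all dofs prescribed to a uniform strain state -> exact Hooke stress
        from arterysim.micromechanics import isotropic_stiffness_mandel

        C6 = np.broadcast_to(isotropic_stiffness_mandel(1.0, 0.25), (1, 8, 6, 6))
        eps = 0.01
        fixed = np.arange(24)
        vals = np.zeros(24)
        vals[0::3] = eps * UNIT_CUBE[:, 0]
        dU = fem.solve_linear_increment(UNIT_CUBE, ONE_HEX, C6,
                                        np.zeros((1, 8, 6)), fixed, vals,
                                        np.zeros(24))
        dNdx, _, _ = fem.shape_gradients_at_gauss(UNIT_CUBE, ONE_HEX)
        grad = np.einsum("egad,eai->egid", dNdx, dU[ONE_HEX[0]][None])
        D6 = tn.to_mandel(0.5 * (grad + np.swapaxes(grad, -1, -2)))
        sig = np.einsum("gij,egj->egi", C6[0], D6)
        expected = tn.to_mandel(tn.from_mandel4(C6[0, 0])[..., 0, 0] * eps)
        assert np.allclose(sig, np.broadcast_to(expected, sig.shape), atol=1e-12)

    def test_internal_force_of_uniform_stress_balances(self):
        s6 = np.zeros((1, 8, 6))
        s6[..., 0] = 1.0
        f = fem.internal_forces(UNIT_CUBE, ONE_HEX, s6).reshape(8, 3)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(np.abs(f[:, 0]), 0.25)  # face tractions of sigma_11

    def test_geometric_stiffness_is_exact_jacobian(self, rng):
        coords = UNIT_CUBE + 0.05 * rng.normal(size=UNIT_CUBE.shape)
        s6 = rng.normal(size=(1, 8, 6))

        def f_int(u):
            return fem.internal_forces(coords + u.reshape(-1, 3), ONE_HEX, s6)

        u0 = 0.01 * rng.normal(size=24)
        K = fem.assemble_geometric_stiffness(coords + u0.reshape(-1, 3),
                                             ONE_HEX, s6).toarray()
        v = rng.normal(size=24)
        h = 1e-6
        fd = (f_int(u0 + h * v) - f_int(u0 - h * v)) / (2 * h)
        assert np.allclose(K @ v, fd, rtol=1e-5, atol=1e-8)


def single_layer_sim(E=0.12, nu=0.3, **mesh_kw):
    """Isotropic cylinder (matrix-only adventitia = same phase as media)."""
    m = msh.build_cylinder_mesh(1.2, 0.19, 0.1, 7.8, **mesh_kw)
    media = mat.MediaMaterial(E, nu)
    adv = mat.AdventitiaMaterial(E, nu, 0.0, 50.0, 0.35, [], [], 0.2, 0.04)
    return fem.Simulation(m, media, adv), m


class TestSolver:
    def test_zero_load_increment(self):
        sim, _ = single_layer_sim(n_circ=8, n_axial=4, n_rad_media=2,
                                  n_rad_adv=1)
        dU = sim.step(0.0, 0.0)
        assert np.allclose(dU, 0.0, atol=1e-12)
        assert np.allclose(sim.stresses6(), 0.0, atol=1e-14)

    def test_lame_thick_cylinder(self):
        sim, m = single_layer_sim(n_circ=24, n_axial=12, n_rad_media=4,
                                  n_rad_adv=4)
        P = 1e-4                                    # MPa: keep strains ~0.5%
                                                    # (Lame is linear theory)
        sim.step(P, 0.0)
        gp = fem.gauss_point_positions(m.nodes, m.elements).reshape(-1, 3)
        S = tn.from_mandel(sim.stresses6().reshape(-1, 6))
        r = np.hypot(gp[:, 0], gp[:, 1])
        mask = np.abs(gp[:, 2] - 3.9) < 1.2         # central region only
        er = np.stack([gp[:, 0] / r, gp[:, 1] / r, 0 * r], -1)
        et = np.stack([-gp[:, 1] / r, gp[:, 0] / r, 0 * r], -1)
        s_r = np.einsum("ni,nij,nj->n", er, S, er)
        s_t = np.einsum("ni,nij,nj->n", et, S, et)
        ri, re = m.r_inner, m.r_outer
        A = P * ri**2 / (re**2 - ri**2)
        B = P * ri**2 * re**2 / (re**2 - ri**2)
        scale = A + B / ri**2                       # max hoop stress
        assert np.max(np.abs(s_r[mask] - (A - B / r[mask] ** 2))) < 0.03 * scale
        assert np.max(np.abs(s_t[mask] - (A + B / r[mask] ** 2))) < 0.03 * scale

    def test_equilibrium_residual_small_after_steps(self):
        sim, _ = single_layer_sim(n_circ=8, n_axial=4, n_rad_media=2,
                                  n_rad_adv=1)
        for P in (0.001, 0.002):
            sim.step(P, 0.0)
        assert sim.equilibrium_residual() < 0.01

    def test_mirror_symmetry_of_fiber_families(self, tiny_config):
        # +-theta pairs: circumferential displacement vanishes on average
        from arterysim import experiments as exp

        sim = exp.make_simulation(tiny_config)
        sim.step(20 * fem.MMHG_TO_MPA, 0.0)
        sim.step(20 * fem.MMHG_TO_MPA, 0.03 * 7.8)
        disp = sim.coords - sim.mesh.nodes
        r0 = np.hypot(sim.mesh.nodes[:, 0], sim.mesh.nodes[:, 1])
        e_t = np.stack([-sim.mesh.nodes[:, 1] / r0,
                        sim.mesh.nodes[:, 0] / r0, 0 * r0], -1)
        u_circ = np.sum(disp * e_t, axis=1)
        assert abs(u_circ.mean()) < 1e-4 * np.abs(disp).max()


class TestMaterialObjectivity:
    def test_small_rigid_rotation_stress_error_second_order(self):
        media = mat.MediaMaterial(1.0, 0.3)
        st = media.init_state(1)
        st.stress6[:] = 0.0
        ang = 1e-5
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        media.update(st, R[None])
        # D = sym(R - I) ~ ang^2/2: stress increment bounded by |C| ang^2
        assert np.max(np.abs(st.stress6)) < 5.0 * ang**2


class TestDriverEquivalence:
    def test_identity_path_constant(self, tiny_config):
        adv = mat.AdventitiaMaterial(0.01, 0.4, 0.15, 50.0, 0.35,
                                     np.radians([60, -60]), np.radians([90, -90]),
                                     0.2, 0.04)
        lrs = np.array([[[1, 0, 0], [0, 0, 1.0], [0, -1.0, 0]]])
        st = adv.init_state(lrs)
        traj = mat.material_point_driver(adv, st, [np.eye(3)] * 3)
        for rec in traj:
            assert np.allclose(rec["stress"], 0.0, atol=1e-14)
            assert np.allclose(rec["theta"], np.radians(60.0), atol=1e-12)

    def test_equibiaxial_isotropic_in_plane(self):
        media = mat.MediaMaterial(0.12, 0.3)
        st = media.init_state(1)
        dF = np.diag([1.01, 1.01, 1.0])
        traj = mat.material_point_driver(media, st, [dF] * 5)
        s = traj[-1]["stress"][0]
        assert s[0, 0] == pytest.approx(s[1, 1], rel=1e-12)
        assert abs(s[0, 1]) < 1e-14

    def test_single_element_fe_matches_driver(self):
        adv = mat.AdventitiaMaterial(0.01, 0.4, 0.15, 50.0, 0.35,
                                     np.radians([60, -60]), np.radians([90, -90]),
                                     0.2, 0.04)
        lrs = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, -1.0, 0]])

        # driver trajectory
        st_drv = adv.init_state(lrs[None])
        path = []
        for _ in range(10):
            d = 0.01
            path.append(np.diag([1 - 0.4 * d, 1 - 0.4 * d, 1 + d]))
        traj = mat.material_point_driver(adv, st_drv, path)

        # FE: one element with all nodes moved affinely by the same dF chain
        st_fe = adv.init_state(np.broadcast_to(lrs, (8, 3, 3)).copy())
        coords = UNIT_CUBE.copy()
        for dF in path:
            dU = coords @ (dF - np.eye(3)).T
            dNdx, _, _ = fem.shape_gradients_at_gauss(coords, ONE_HEX)
            grad = np.einsum("egad,eai->egid", dNdx, dU[ONE_HEX[0]][None])
            adv.update(st_fe, grad.reshape(-1, 3, 3) + np.eye(3))
            coords = coords + dU
        assert np.allclose(st_fe.stress6[0],
                           tn.to_mandel(traj[-1]["stress"][0]), atol=1e-8)
        assert np.allclose(st_fe.eps_chord[0], st_drv.eps_chord[0], atol=1e-8)
        assert np.allclose(st_fe.triads[0], st_drv.triads[0], atol=1e-8)
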