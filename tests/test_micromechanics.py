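"""Eshelby cylinder, Mori-Tanaka concentrations, spin operators, tangent."""

import numpy as np
import pytest

from arterysim import micromechanics as mm
from arterysim import tensors as tn
from conftest import random_rotation

E1 = np.array([1.0, 0.0, 0.0])
E3 = np.array([0.0, 0.0, 1.0])


def voigt_dilute_oracle(S4, Cm4, Ci4):
    """Independent dilute-concentration computation in Voigt bookkeeping.

    Uses engineering-shear Voigt vectors (strain factors 2) so that none of
    the package's Mandel code is involved.
    """
    idx = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]

    def mat(T):                       # stress-strain Voigt matrix
        M = np.zeros((6, 6))
        for a, (i, j) in enumerate(idx):
            for b, (k, l) in enumerate(idx):
                fac = 1.0 if b < 3 else 2.0      # engineering shear strain
                M[a, b] = fac * T[i, j, k, l]
        return M

    bracket = np.eye(6) + mat(S4) @ np.linalg.inv(mat(Cm4)) @ (mat(Ci4) - mat(Cm4))
    A = np.linalg.inv(bracket)
    out = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(idx):
        for b, (k, l) in enumerate(idx):
            fac = 1.0 if b < 3 else 0.5          # back to tensor components
            out[i, j, k, l] = out[j, i, k, l] = fac * A[a, b]
            out[i, j, l, k] = out[j, i, l, k] = fac * A[a, b]
    return out


class TestEshelbyCylinder:
    def test_closed_form_components_nu_04(self):
        nu = 0.4
        S = mm.eshelby_cylinder(nu, E1)
        assert S[1, 1, 1, 1] == pytest.approx((5 - 4 * nu) / (8 * (1 - nu)), abs=1e-10)
        assert S[0, 0, 0, 0] == pytest.approx(0.0, abs=1e-10)
        assert S[0, 1, 0, 1] == pytest.approx(0.25, abs=1e-10)
        assert S[1, 1, 0, 0] == pytest.approx(nu / (2 * (1 - nu)), abs=1e-10)
        assert S[1, 2, 1, 2] == pytest.approx((3 - 4 * nu) / (8 * (1 - nu)), abs=1e-10)

    def test_closed_form_nu_zero(self):
        S = mm.eshelby_cylinder(0.0, E1)
        assert S[1, 1, 2, 2] == pytest.approx(-0.125, abs=1e-10)

    def test_frame_covariance(self, rng):
        S1 = mm.eshelby_cylinder(0.3, E1)
        r = random_rotation(rng)
        axis = r @ E1
        direct = mm.eshelby_cylinder(0.3, axis)
        # covariance: components along the rotated axis still vanish
        assert np.einsum("i,j,k,l,ijkl->", axis, axis, axis, axis,
                         direct) == pytest.approx(0.0, abs=1e-10)
        S3 = mm.eshelby_cylinder(0.3, E3)
        assert S3[0, 0, 0, 0] == pytest.approx(S1[1, 1, 1, 1], abs=1e-10)

    def test_rejects_near_incompressible_matrix(self):
        with pytest.raises(ValueError):
            mm.eshelby_cylinder(0.499, E1)


class TestDiluteConcentration:
    def test_identical_phases_give_identity(self):
        C = mm.ElasticPhase(1.0, 0.3).stiffness
        S = mm.eshelby_cylinder(0.3, E1)
        A = mm.dilute_concentration(S, C, C)
        assert np.allclose(A, tn.from_mandel4(np.eye(6)), atol=1e-12)

    def test_vanishing_inclusion_limit(self):
        Cm = mm.ElasticPhase(1.0, 0.3)
        S = mm.eshelby_cylinder(0.3, E1)
        A = mm.dilute_concentration(S, Cm.stiffness,
                                    mm.ElasticPhase(1e-9, 0.3).stiffness)
        S6 = tn.to_mandel4(S)
        expected = np.linalg.inv(np.eye(6) - S6)
        assert np.allclose(tn.to_mandel4(A), expected, atol=1e-6)

    def test_matches_independent_voigt_oracle(self):
        Cm = mm.ElasticPhase(0.01, 0.4).stiffness
        Ci = mm.ElasticPhase(1.2, 0.35).stiffness
        S = mm.eshelby_cylinder(0.4, np.array([0.6, 0.8, 0.0]))
        ours = mm.dilute_concentration(S, Cm, Ci)
        oracle = voigt_dilute_oracle(S, Cm, Ci)
        assert np.allclose(ours, oracle, atol=1e-10)


def two_family_rve(f_c=0.15, E_i=1.0, theta=60.0, E_m=0.01, nu_m=0.4):
    th = np.radians(theta)
    a1 = np.array([np.sin(th), np.cos(th), 0.0])
    a2 = np.array([-np.sin(th), np.cos(th), 0.0])
    phase = mm.ElasticPhase(E_i, 0.35)
    return mm.RVEModel(mm.ElasticPhase(E_m, nu_m), [
        mm.FiberInclusion(phase, a1, f_c / 2),
        mm.FiberInclusion(phase, a2, f_c / 2),
    ])


class TestMoriTanaka:
    def test_identical_phases(self):
        rve = two_family_rve(E_i=0.01, E_m=0.01, nu_m=0.35)
        # equal moduli but different Poisson ratios -> not identity; use same
        phase = mm.ElasticPhase(0.01, 0.4)
        rve = mm.RVEModel(phase, [mm.FiberInclusion(phase, E1, 0.1)])
        conc = mm.mt_concentrations(rve)
        for A in conc.values():
            assert np.allclose(A, tn.from_mandel4(np.eye(6)), atol=1e-12)

    def test_vanishing_fraction_matrix_identity(self):
        rve = two_family_rve(f_c=1e-12)
        conc = mm.mt_concentrations(rve)
        assert np.allclose(conc["matrix"], tn.from_mandel4(np.eye(6)), atol=1e-9)

    def test_sum_rule(self):
        rve = two_family_rve(f_c=0.3, E_i=50.0)
        conc = mm.mt_concentrations(rve)
        total = rve.f_matrix * tn.to_mandel4(conc["matrix"])
        for i, inc in enumerate(rve.inclusions):
            total += inc.volume_fraction * tn.to_mandel4(conc[i])
        assert np.allclose(total, np.eye(6), atol=1e-10)

    def test_mirror_families_give_mirror_strains(self):
        rve = two_family_rve(f_c=0.2, E_i=5.0)
        conc = mm.mt_concentrations(rve)
        D = np.diag([0.01, 0.03, -0.01])           # axisymmetric about e2
        d1 = np.einsum("ijkl,kl->ij", conc[0], D)
        d2 = np.einsum("ijkl,kl->ij", conc[1], D)
        M = np.diag([-1.0, 1.0, 1.0])              # mirror x -> -x
        assert np.allclose(d2, M @ d1 @ M, atol=1e-12)

    def test_dilute_limit_agreement(self):
        f = 1e-4
        rve = two_family_rve(f_c=f, E_i=5.0)
        conc = mm.mt_concentrations(rve)
        Cm6 = rve.matrix.stiffness_mandel
        S6 = tn.to_mandel4(mm.eshelby_cylinder(0.4, rve.inclusions[0].axis))
        A_dil = mm.dilute_concentration_mandel(
            S6, Cm6, rve.inclusions[0].phase.stiffness_mandel)
        assert np.allclose(tn.to_mandel4(conc[0]), A_dil, atol=10 * f)


class TestSpinConcentration:
    def test_identical_phases_no_spin(self):
        phase = mm.ElasticPhase(0.01, 0.4)
        rve = mm.RVEModel(phase, [mm.FiberInclusion(phase, E1, 0.1)])
        R = mm.spin_concentration(rve, 0)
        assert np.max(np.abs(R)) < 1e-12

    def test_axis_aligned_with_principal_direction(self):
        rve = mm.RVEModel(mm.ElasticPhase(0.01, 0.4),
                          [mm.FiberInclusion(mm.ElasticPhase(1.0, 0.35), E1, 0.1)])
        fields = mm.phase_fields(rve, np.diag([0.02, -0.01, -0.01]))
        _, w = fields[0]
        assert np.max(np.abs(w)) < 1e-12

    def test_inclined_stiff_fiber_rotates_toward_stretch(self):
        a = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        rve = mm.RVEModel(mm.ElasticPhase(0.01, 0.4),
                          [mm.FiberInclusion(mm.ElasticPhase(10.0, 0.35), a, 0.1)])
        D = 1e-3 * np.diag([1.0, 0.0, 0.0])
        d, w = mm.phase_fields(rve, D)[0]
        assert np.allclose(w, -w.T, atol=1e-15)    # spin is antisymmetric
        # spin axis perpendicular to the stretch-fiber plane (only w_12 != 0)
        assert abs(w[0, 2]) < 1e-12 and abs(w[1, 2]) < 1e-12
        c_new = a + (d + w) @ a
        c_new /= np.linalg.norm(c_new)
        assert np.arccos(abs(c_new[0])) < np.arccos(abs(a[0]))  # toward e1

    def test_antisymmetric_for_any_symmetric_input(self, rng):
        rve = two_family_rve(E_i=3.0)
        Rop = mm.spin_concentration(rve, 1)
        D = rng.normal(size=(3, 3))
        D = 0.5 * (D + D.T)
        w = np.einsum("ijm,m->ij", Rop, tn.to_mandel(D))
        assert np.allclose(w, -w.T, atol=1e-14)


class TestHomogenizedTangent:
    def test_no_fibers_returns_matrix(self):
        rve = mm.RVEModel(mm.ElasticPhase(0.01, 0.4), [])
        C = mm.homogenized_tangent(rve, {"matrix": np.zeros((3, 3))})
        assert np.allclose(C, rve.matrix.stiffness, atol=1e-14)

    def test_axial_modulus_between_bounds(self):
        e2 = np.array([0.0, 1.0, 0.0])
        rve = mm.RVEModel(mm.ElasticPhase(0.01, 0.3),
                          [mm.FiberInclusion(mm.ElasticPhase(1.0, 0.3), e2, 0.2)])
        zeros = {"matrix": np.zeros((3, 3)), 0: np.zeros((3, 3))}
        C6 = tn.to_mandel4(mm.homogenized_tangent(rve, zeros))
        # axial Young modulus from the compliance along e2
        E_ax = 1.0 / np.linalg.inv(C6)[1, 1]
        reuss = 1.0 / (0.8 / 0.01 + 0.2 / 1.0)
        voigt = 0.8 * 0.01 + 0.2 * 1.0
        assert reuss < E_ax < voigt

    def test_zero_stress_composition_matches_hand_product(self):
        rve = mm.RVEModel(mm.ElasticPhase(0.01, 0.4),
                          [mm.FiberInclusion(mm.ElasticPhase(2.0, 0.35), E1, 0.25)])
        zeros = {"matrix": np.zeros((3, 3)), 0: np.zeros((3, 3))}
        C6 = tn.to_mandel4(mm.homogenized_tangent(rve, zeros))
        conc = mm.mt_concentrations(rve)
        hand = (0.75 * rve.matrix.stiffness_mandel @ tn.to_mandel4(conc["matrix"])
                + 0.25 * rve.inclusions[0].phase.stiffness_mandel
                @ tn.to_mandel4(conc[0]))
        assert np.allclose(C6, hand, atol=1e-10)
        # major symmetry holds at zero phase stress for the aligned family
        assert np.allclose(C6, C6.T, atol=1e-9)

    def test_transverse_isotropy_about_single_family_axis(self):
        rve = mm.RVEModel(mm.ElasticPhase(0.01, 0.4),
                          [mm.FiberInclusion(mm.ElasticPhase(1.0, 0.35), E3, 0.2)])
        zeros = {"matrix": np.zeros((3, 3)), 0: np.zeros((3, 3))}
        C = mm.homogenized_tangent(rve, zeros)
        ang = 0.7
        r = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        assert np.allclose(tn.rotate4(C, r), C, atol=1e-10)

    def test_minor_symmetries_with_phase_stresses(self, rng):
        rve = two_family_rve(E_i=5.0)
        t1 = rng.normal(size=(3, 3)); t1 = 0.5 * (t1 + t1.T)
        t2 = rng.normal(size=(3, 3)); t2 = 0.5 * (t2 + t2.T)
        tm = rng.normal(size=(3, 3)); tm = 0.5 * (tm + tm.T)
        C = mm.homogenized_tangent(rve, {"matrix": tm, 0: t1, 1: t2})
        assert tn.is_minor_symmetric(C)

    def test_rejects_missing_phase_stress(self):
        rve = two_family_rve()
        with pytest.raises(ValueError):
            mm.homogenized_tangent(rve, {"matrix": np.zeros((3, 3))})


class TestPhaseFields:
    def test_zero_input(self):
        rve = two_family_rve(E_i=2.0)
        fields = mm.phase_fields(rve, np.zeros((3, 3)))
        for d, w in fields.values():
            assert np.allclose(d, 0.0) and np.allclose(w, 0.0)

    def test_strain_rate_average_rule(self, rng):
        rve = two_family_rve(f_c=0.25, E_i=8.0, theta=47.0)
        D = rng.normal(size=(3, 3))
        D = 0.5 * (D + D.T)
        fields = mm.phase_fields(rve, D)
        total = rve.f_matrix * fields["matrix"][0]
        w_total = rve.f_matrix * fields["matrix"][1]
        for i, inc in enumerate(rve.inclusions):
            total = total + inc.volume_fraction * fields[i][0]
            w_total = w_total + inc.volume_fraction * fields[i][1]
        assert np.allclose(total, D, atol=1e-10)
        assert np.allclose(w_total, 0.0, atol=1e-10)   # pure straining imposed
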