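"""Explicit incremental finite-element solver for the tension-inflation problem.

Each load increment solves the linearized weak form with the tangent frozen
at step n,

    int_O  D(dU) : C_n : D(v) dO  =  int_Si P_{n+1} n . v dS - int_O T_n : D(v) dO ,

on the current (updated-Lagrangian) geometry, then performs the staggered
constitutive update per Gauss point with the computed incremental
displacement and finally moves the mesh.  Pressure is a follower load:
it is integrated over the current inner surface every increment.  Boundary
conditions follow the tension-inflation protocol: the left end section is
fully clamped, the right end section gets a prescribed (purely axial)
displacement increment, and the outer surface is traction-free.

Elements are 8-node hexahedra with full 2x2x2 Gauss quadrature; the linear
systems are solved by direct sparse factorization.  The per-step
linearization error of the explicit scheme is controlled by the load-step
sizes (a rigid rotation of magnitude eps produces a spurious strain of
order eps^2 per increment).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from . import tensors as tn
from .material import AdventitiaMaterial, MediaMaterial
from .mesh import Mesh

__all__ = [
    "MMHG_TO_MPA",
    "shape_gradients_at_gauss",
    "gauss_point_positions",
    "assemble_stiffness",
    "internal_forces",
    "pressure_forces",
    "facet_areas",
    "solve_linear_increment",
    "Simulation",
]

#: unit conversion used throughout: lengths in mm, stresses in MPa, forces in N.
MMHG_TO_MPA = 133.322e-6

_G1 = 1.0 / np.sqrt(3.0)
# 2x2x2 Gauss abscissae (unit weights) and hex8 natural node coordinates
_GP = np.array([(x, y, z) for z in (-_G1, _G1) for y in (-_G1, _G1)
                for x in (-_G1, _G1)])
_XI_N = np.array([
    (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
    (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
], dtype=float)


def _shape_funcs(points: np.ndarray):
    """Hex8 shape functions and natural-coordinate gradients at ``points``."""
    xi = points[:, None, :]            # (G, 1, 3)
    xn = _XI_N[None, :, :]             # (1, 8, 3)
    terms = 1.0 + xi * xn              # (G, 8, 3)
    N = 0.125 * terms.prod(axis=-1)
    dN = np.empty((len(points), 8, 3))
    for d in range(3):
        others = [i for i in range(3) if i != d]
        dN[:, :, d] = 0.125 * xn[:, :, d] * terms[:, :, others].prod(axis=-1)
    return N, dN


_N_GP, _DN_GP = _shape_funcs(_GP)


def shape_gradients_at_gauss(coords: np.ndarray, elements: np.ndarray):
    """Spatial shape-function gradients, Jacobian determinants and weights.

    Returns ``(dNdx (E,8,8,3), detJ (E,8), w (8,))`` for 2x2x2 quadrature
    (axis 1 is the Gauss point, axis 2 the element node).
    """
    xe = coords[elements]                                   # (E, 8, 3)
    J = np.einsum("gad,eai->egdi", _DN_GP, xe)              # (E, G, 3, 3)
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    # J[d, i] = dx_i/dxi_d, so dN/dx_i = dN/dxi_d * (J^-1)[i, d]
    dNdx = np.einsum("gad,egid->egai", _DN_GP, Jinv)
    return dNdx, detJ, np.ones(8)


def gauss_point_positions(coords: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """(E, 8, 3) spatial positions of the Gauss points."""
    return np.einsum("ga,eai->egi", _N_GP, coords[elements])


_SQ2 = np.sqrt(2.0)


def _b_matrices(dNdx: np.ndarray) -> np.ndarray:
    """Mandel strain-displacement matrices, (E, G, 6, 24)."""
    E, G = dNdx.shape[:2]
    B = np.zeros((E, G, 6, 24))
    a = np.arange(8)
    B[:, :, 0, 3 * a + 0] = dNdx[..., 0]
    B[:, :, 1, 3 * a + 1] = dNdx[..., 1]
    B[:, :, 2, 3 * a + 2] = dNdx[..., 2]
    B[:, :, 3, 3 * a + 1] = dNdx[..., 2] / _SQ2
    B[:, :, 3, 3 * a + 2] = dNdx[..., 1] / _SQ2
    B[:, :, 4, 3 * a + 0] = dNdx[..., 2] / _SQ2
    B[:, :, 4, 3 * a + 2] = dNdx[..., 0] / _SQ2
    B[:, :, 5, 3 * a + 0] = dNdx[..., 1] / _SQ2
    B[:, :, 5, 3 * a + 1] = dNdx[..., 0] / _SQ2
    return B


def _element_dofs(elements: np.ndarray) -> np.ndarray:
    return (3 * elements[:, :, None] + np.arange(3)).reshape(len(elements), 24)


def assemble_stiffness(coords, elements, tangent6) -> sparse.csr_matrix:
    """Global stiffness from per-Gauss-point Mandel tangents (E, 8, 6, 6)."""
    dNdx, detJ, _ = shape_gradients_at_gauss(coords, elements)
    B = _b_matrices(dNdx)
    Ke = np.einsum("egia,egij,egjb,eg->eab", B, tangent6, B, detJ, optimize=True)
    edof = _element_dofs(elements)
    rows = np.repeat(edof[:, :, None], 24, axis=2)
    cols = np.repeat(edof[:, None, :], 24, axis=1)
    n = 3 * coords.shape[0]
    K = sparse.coo_matrix((Ke.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n))
    return K.tocsr()


def internal_forces(coords, elements, stress6) -> np.ndarray:
    """Internal nodal force vector from per-Gauss-point Mandel stresses."""
    dNdx, detJ, _ = shape_gradients_at_gauss(coords, elements)
    B = _b_matrices(dNdx)
    fe = np.einsum("egia,egi,eg->ea", B, stress6, detJ, optimize=True)
    f = np.zeros(3 * coords.shape[0])
    np.add.at(f, _element_dofs(elements), fe)
    return f


_QP2 = np.array([(x, y) for y in (-_G1, _G1) for x in (-_G1, _G1)])
_XI_Q = np.array([(-1, -1), (1, -1), (1, 1), (-1, 1)], dtype=float)
_NQ = 0.25 * (1 + _QP2[:, None, 0] * _XI_Q[None, :, 0]) * \
      (1 + _QP2[:, None, 1] * _XI_Q[None, :, 1])
_DNQ = np.stack([
    0.25 * _XI_Q[None, :, 0] * (1 + _QP2[:, None, 1] * _XI_Q[None, :, 1]),
    0.25 * _XI_Q[None, :, 1] * (1 + _QP2[:, None, 0] * _XI_Q[None, :, 0]),
], axis=-1)                                                  # (G, 4, 2)


def _facet_darea(coords, facets):
    """Per-facet, per-Gauss-point oriented area vectors (F, G, 3)."""
    xf = coords[facets]                                      # (F, 4, 3)
    t = np.einsum("gad,fai->fgdi", _DNQ, xf)                 # (F, G, 2, 3)
    return np.cross(t[:, :, 0, :], t[:, :, 1, :])


def facet_areas(coords, facets) -> np.ndarray:
    """Facet areas by 2x2 quadrature."""
    return np.linalg.norm(_facet_darea(coords, facets), axis=-1).sum(axis=-1)


def pressure_forces(coords, facets, pressure: float) -> np.ndarray:
    """Consistent nodal forces of a uniform pressure on oriented facets.

    The facet node ordering fixes the direction of the parametric area
    vector; for the inner-surface facets of :func:`~arterysim.mesh.
    build_cylinder_mesh` it points radially outward, so a positive pressure
    inflates the cylinder.
    """
    dA = _facet_darea(coords, facets)                        # (F, G, 3)
    fa = pressure * np.einsum("ga,fgi->fai", _NQ, dA)        # (F, 4, 3)
    f = np.zeros(3 * coords.shape[0])
    np.add.at(f, (3 * facets[:, :, None] + np.arange(3)), fa)
    return f


def assemble_geometric_stiffness(coords, elements, stress6) -> sparse.csr_matrix:
    """Initial-stress (geometric) stiffness consistent with a frozen trial stress.

    Within one increment the trial Cauchy stress at a Gauss point does not
    depend on the current geometry (the strain increment is measured on the
    step-start configuration), so the geometric part of the internal-force
    Jacobian comes solely from the variation of the spatial gradients and
    the volume element::

        K_geo[3a+i, 3b+k] = int sigma_ij ( dN_a/dx_j dN_b/dx_k
                                          - dN_b/dx_j dN_a/dx_k ) dO .

    The first term is the volume-change contribution, the second the
    convection of the test-function gradient.  With fiber stresses larger
    than the tangent moduli this term is what keeps the frozen-tangent
    equilibrium iteration convergent.
    """
    dNdx, detJ, _ = shape_gradients_at_gauss(coords, elements)
    sig = tn.from_mandel(stress6)
    ga = np.einsum("egij,egaj->egai", sig, dNdx, optimize=True)  # (sigma . grad N_a)_i
    k1 = np.einsum("egai,egbk,eg->eaibk", ga, dNdx, detJ, optimize=True)
    k2 = np.einsum("egbi,egak,eg->eaibk", ga, dNdx, detJ, optimize=True)
    Ke = (k1 - k2).reshape(len(elements), 24, 24)
    edof = _element_dofs(elements)
    rows = np.repeat(edof[:, :, None], 24, axis=2)
    cols = np.repeat(edof[:, None, :], 24, axis=1)
    n = 3 * coords.shape[0]
    K = sparse.coo_matrix((Ke.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n))
    return K.tocsr()


def pressure_load_stiffness(coords, facets, pressure: float) -> sparse.csr_matrix:
    """Jacobian of the follower pressure load with respect to nodal motion.

    With ``f_a = P sum_g w N_a (t1 x t2)`` and the tangents ``t1, t2`` linear
    in the facet coordinates, ``d(t1 x t2)/dx_bk = dN1_b (e_k x t2)
    + dN2_b (t1 x e_k)``.  At physiological pressures this stiffness rivals
    the matrix modulus of the soft adventitia, so omitting it stalls the
    equilibrium iteration during inflation.
    """
    xf = coords[facets]                                       # (F, 4, 3)
    t = np.einsum("gad,fai->fgdi", _DNQ, xf)                  # (F, G, 2, 3)
    eps = np.zeros((3, 3, 3))
    eps[0, 1, 2] = eps[1, 2, 0] = eps[2, 0, 1] = 1.0
    eps[0, 2, 1] = eps[1, 0, 2] = eps[2, 1, 0] = -1.0
    c1 = np.einsum("ikm,fgm->fgik", eps, t[:, :, 1, :])       # (e_k x t2)_i
    c2 = np.einsum("imk,fgm->fgik", eps, t[:, :, 0, :])       # (t1 x e_k)_i
    Ke = pressure * (
        np.einsum("ga,gb,fgik->faibk", _NQ, _DNQ[:, :, 0], c1)
        + np.einsum("ga,gb,fgik->faibk", _NQ, _DNQ[:, :, 1], c2)
    ).reshape(len(facets), 12, 12)
    fdof = (3 * facets[:, :, None] + np.arange(3)).reshape(len(facets), 12)
    rows = np.repeat(fdof[:, :, None], 12, axis=2)
    cols = np.repeat(fdof[:, None, :], 12, axis=1)
    n = 3 * coords.shape[0]
    K = sparse.coo_matrix((Ke.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n))
    return K.tocsr()


def solve_linear_increment(coords, elements, tangent6, stress6,
                           fixed_dofs, fixed_vals, f_ext) -> np.ndarray:
    """One linear solve of the frozen-tangent weak form; returns dU (N, 3).

    ``fixed_dofs``/``fixed_vals`` prescribe incremental displacement
    components; the right-hand side is the external load minus the internal
    forces of the step-n stress state.
    """
    n = 3 * coords.shape[0]
    K = assemble_stiffness(coords, elements, tangent6)
    rhs = f_ext - internal_forces(coords, elements, stress6)
    fixed = np.zeros(n, dtype=bool)
    fixed[fixed_dofs] = True
    if not fixed.any():
        raise ValueError("no Dirichlet constraints: singular stiffness")
    u = np.zeros(n)
    u[fixed_dofs] = fixed_vals
    free = ~fixed
    rhs_f = rhs[free] - K[free][:, fixed] @ u[fixed]
    u[free] = spsolve(K[free][:, free].tocsc(), rhs_f)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("singular stiffness system (insufficient BCs?)")
    return u.reshape(-1, 3)


class Simulation:
    """Incremental tension-inflation simulation on a two-layer cylinder mesh.

    Owns the current nodal coordinates, the per-layer Gauss-point material
    states and the current pressure; :meth:`step` advances one load
    increment (new pressure value and axial end-displacement increment).
    """

    def __init__(self, mesh: Mesh, media: MediaMaterial,
                 adventitia: AdventitiaMaterial):
        self.mesh = mesh
        self.coords = mesh.nodes.copy()
        self.media = media
        self.adventitia = adventitia
        self.media_els = np.where(mesh.layer == 0)[0]
        self.adv_els = np.where(mesh.layer == 1)[0]
        self.state_media = media.init_state(8 * len(self.media_els))
        gp = gauss_point_positions(self.coords, mesh.elements[self.adv_els])
        self.state_adv = self.adventitia.init_state(
            self._initial_lrs(gp.reshape(-1, 3)))
        self.pressure = 0.0       # MPa
        self.axial_displacement = 0.0
        self.n_steps = 0
        self.last_residual = np.nan
        self._alpha_hint = 1.0

    @staticmethod
    def _initial_lrs(points: np.ndarray) -> np.ndarray:
        r = np.hypot(points[:, 0], points[:, 1])
        e_r = np.stack([points[:, 0] / r, points[:, 1] / r, np.zeros(len(r))], -1)
        e_t = np.stack([-points[:, 1] / r, points[:, 0] / r, np.zeros(len(r))], -1)
        e_z = np.broadcast_to([0.0, 0.0, 1.0], e_r.shape)
        return np.stack([e_t, e_z, e_r], axis=-2)       # rows K, T, N

    # -- gathering per-element-GP fields -------------------------------------

    def _gathered(self, attr_media, attr_adv):
        E = len(self.mesh.elements)
        shape = attr_adv.shape[1:] if len(self.adv_els) else attr_media.shape[1:]
        out = np.empty((E, 8) + shape)
        if len(self.media_els):
            out[self.media_els] = attr_media.reshape(len(self.media_els), 8, *shape)
        if len(self.adv_els):
            out[self.adv_els] = attr_adv.reshape(len(self.adv_els), 8, *shape)
        return out

    def tangents(self) -> np.ndarray:
        return self._gathered(self.state_media.tangent6, self.state_adv.tangent6)

    def stresses6(self) -> np.ndarray:
        return self._gathered(self.state_media.stress6, self.state_adv.stress6)

    # -- one increment --------------------------------------------------------

    def step(self, pressure: float, d_axial: float = 0.0,
             rtol: float = 1e-5, max_iter: int = 60) -> np.ndarray:
        """Advance to pressure ``pressure`` (MPa) with an axial end-displacement
        increment ``d_axial`` (mm); returns the incremental displacement field.

        The increment solves the weak form with the constitutive tangent
        frozen at step n.  Because the end-of-increment configuration enters
        the balance (follower pressure, integrals over the updated domain),
        the linear solve is repeated — same frozen tangent, plus the
        initial-stress stiffness of the trial state, with a backtracking
        line search guarding against overshoot and element inversion —
        until the out-of-balance force drops below ``rtol`` times the load
        scale (external load or end reactions, whichever is larger).  The
        staggered structure is untouched: the microstructure and the tangent
        are updated once, after the increment has equilibrated.
        """
        mesh = self.mesh
        coords0 = self.coords
        T6_0 = self.stresses6()
        C6 = self.tangents()
        dNdx0, _, _ = shape_gradients_at_gauss(coords0, mesh.elements)
        B0 = _b_matrices(dNdx0)

        n = 3 * len(coords0)
        fixed = np.zeros(n, dtype=bool)
        ufix = np.zeros(n)
        for nid in mesh.sigma_minus:
            fixed[3 * nid:3 * nid + 3] = True
        for nid in mesh.sigma_plus:
            fixed[3 * nid:3 * nid + 3] = True
            ufix[3 * nid + 2] = d_axial
        free = ~fixed

        def trial(dU):
            """Residual and trial stress of a candidate increment field."""
            coords_cur = coords0 + dU
            D6 = np.einsum("egiq,eq->egi", B0, dU[mesh.elements].reshape(-1, 24))
            T6_trial = T6_0 + np.einsum("egij,egj->egi", C6, D6)
            f_ext = pressure_forces(coords_cur, mesh.inner_facets, pressure)
            res = f_ext - internal_forces(coords_cur, mesh.elements, T6_trial)
            denom = max(np.linalg.norm(f_ext[free]), np.linalg.norm(res[fixed]),
                        1e-12)
            return np.linalg.norm(res[free]) / denom, res, T6_trial, coords_cur

        def inverts(dU):
            # reject near-inverted increments too: a vanishing det makes the
            # current-configuration Jacobians numerically singular
            grad = np.einsum("egad,eai->egid", dNdx0, dU[mesh.elements])
            det = np.linalg.det(np.eye(3) + grad)
            return not np.all(np.isfinite(det)) or np.any(det <= 0.05)

        # initial guess: affine axial stretch profile (satisfies the Dirichlet
        # data smoothly instead of jumping at the loaded end section)
        dU = np.zeros_like(coords0)
        if d_axial != 0.0:
            zmax = coords0[:, 2].max()
            dU[:, 2] = d_axial * coords0[:, 2] / zmax
        resnorm, res, T6_trial, coords_cur = trial(dU)
        self._alpha_hint = 1.0
        for it in range(max_iter):
            if it > 0 and resnorm < rtol:
                break
            K = (assemble_stiffness(coords_cur, mesh.elements, C6)
                 + assemble_geometric_stiffness(coords_cur, mesh.elements,
                                                T6_trial)
                 - pressure_load_stiffness(coords_cur, mesh.inner_facets,
                                           pressure))
            Kff = K[free][:, free].tocsc()
            diag_scale = np.abs(Kff.diagonal()).mean()

            def line_search(du):
                # warm-started backtracking: begin near the last accepted
                # step length instead of re-probing the full step each time
                best, alpha = None, self._alpha_hint
                for _ in range(10):
                    cand = dU + alpha * du
                    if not inverts(cand):
                        try:
                            rn_c, *rest = trial(cand)
                        except np.linalg.LinAlgError:
                            rn_c = np.inf
                        if np.isfinite(rn_c) and (best is None or rn_c < best[0]):
                            best = (rn_c, cand, *rest, alpha)
                        if rn_c < resnorm:
                            break
                    alpha *= 0.5
                if best is not None and best[0] < resnorm:
                    self._alpha_hint = min(1.0, 2.0 * best[-1])
                    best = best[:-1]
                elif best is not None:
                    best = best[:-1]
                return best

            # pure Newton first; near spurious singular points (heavily
            # stressed nonsymmetric tangent) fall back to damped systems,
            # but only while the residual is still appreciable — stagnating
            # below stall_tol is accepted as converged-enough for the step
            stall_tol = 1e-3
            best = None
            for mu in (0.0, 1e-3, 1e-1, 10.0):
                if mu > 0.0 and resnorm < stall_tol:
                    break
                Ksolve = Kff if mu == 0.0 else (
                    Kff + mu * diag_scale * sparse.identity(Kff.shape[0],
                                                            format="csc"))
                du = np.zeros(n)
                du[free] = spsolve(Ksolve, res[free])
                if not np.all(np.isfinite(du)):
                    continue
                best = line_search(du.reshape(-1, 3))
                if best is not None and best[0] < resnorm:
                    break
            if best is None or best[0] >= resnorm:
                break   # stagnated: keep the current (best) increment
            resnorm, dU, res, T6_trial, coords_cur = best
        self.last_residual = resnorm
        self.last_iterations = it

        self._constitutive_update(dU)
        self.coords = coords0 + dU
        self.pressure = pressure
        self.axial_displacement += d_axial
        self.n_steps += 1
        return dU

    def _constitutive_update(self, dU: np.ndarray) -> None:
        # strain increments are measured on the step-start configuration
        # (dF = I + grad dU), consistently with the trial stress above
        dNdx, _, _ = shape_gradients_at_gauss(self.coords, self.mesh.elements)
        ue = dU[self.mesh.elements]                           # (E, 8, 3)
        grad = np.einsum("egad,eai->egid", dNdx, ue)          # spatial grad dU
        dF = np.eye(3) + grad
        if len(self.media_els):
            self.media.update(self.state_media,
                              dF[self.media_els].reshape(-1, 3, 3))
        if len(self.adv_els):
            self.adventitia.update(self.state_adv,
                                   dF[self.adv_els].reshape(-1, 3, 3))

    def equilibrium_residual(self) -> float:
        """Out-of-balance force of the current state on the current geometry,
        relative to the external load norm (global equilibrium diagnostic)."""
        f_ext = pressure_forces(self.coords, self.mesh.inner_facets, self.pressure)
        f_int = internal_forces(self.coords, self.mesh.elements, self.stresses6())
        res = f_ext - f_int
        free = np.ones(3 * len(self.coords), dtype=bool)
        for nid in np.concatenate([self.mesh.sigma_minus, self.mesh.sigma_plus]):
            free[3 * nid:3 * nid + 3] = False
        denom = max(np.linalg.norm(f_ext[free]), 1e-12)
        return float(np.linalg.norm(res[free]) / denom)
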