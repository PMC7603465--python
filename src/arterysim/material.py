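"""Material-point state and the staggered constitutive update.

One increment of the staggered scheme does, per Gauss point and in order:

1. macroscopic stress update ``T <- T + C_n : D`` with the frozen tangent,
2. convection of the wall triad (K, T, N) with the incremental deformation
   gradient,
3. evaluation of the per-family micro strain rates and spins from the
   cached concentration operators of step n,
4. phase Cauchy stress updates (Jaumann rates converted to material rates
   with the phase spins),
5. fiber-triad evolution by the normalized explicit update,
6. chord-strain accumulation and crimp-geometry/recruitment update,
7. rebuild of the concentration operators and of the homogenized tangent
   for step n+1.

Medial points are homogeneous isotropic and only perform step 1 (their
tangent is constant).  Everything is vectorized over the Gauss points of a
layer; ``MaterialPointState`` is a struct-of-arrays batch.

The pipeline uses a unit pseudo-time step: strain-*rate* tensors ARE the
per-increment strain tensors (the loading is quasi-static and the material
rate-independent).  By default the macroscopic stress update is the literal
forward-Euler form without macroscopic Jaumann convection; pass
``corotational=True`` to add the macroscopic spin convection to the
macroscopic and phase stresses and to the fiber triads (useful when a load
path involves appreciable rigid rotation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import fiber_model as fib
from . import kinematics as kin
from . import micromechanics as mm
from . import tensors as tn

__all__ = ["MediaMaterial", "AdventitiaMaterial", "MaterialPointState",
           "material_point_driver"]


@dataclass
class MaterialPointState:
    """Batched state of the material points of one layer (struct of arrays)."""

    stress6: np.ndarray                  # (N, 6) macroscopic Cauchy stress, Mandel
    F: np.ndarray                        # (N, 3, 3) deformation gradient
    tangent6: np.ndarray                 # (N, 6, 6) homogenized tangent
    lrs: np.ndarray = None               # (N, 3, 3) wall triad rows (K, T, N)
    triads: np.ndarray = None            # (N, nf, 3, 3) fiber triads rows (c, pc, Nc)
    eps_chord: np.ndarray = None         # (N, nf) accumulated chord strains
    E_ratio: np.ndarray = None           # (N, nf) chord modulus / straight modulus
    crimp_k: np.ndarray = None           # (N, nf) current crimp ratio h/ell
    t_phase: np.ndarray = None           # (N, nf+1, 3, 3) family stresses + matrix last
    cache: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.stress6)

    def stress(self) -> np.ndarray:
        return tn.from_mandel(self.stress6)


class MediaMaterial:
    """Homogeneous isotropic hypoelastic layer."""

    def __init__(self, E: float, nu: float, corotational: bool = False):
        self.phase = mm.ElasticPhase(E, nu)
        self.C6 = self.phase.stiffness_mandel
        self.corotational = corotational

    def init_state(self, n_points: int) -> MaterialPointState:
        return MaterialPointState(
            stress6=np.zeros((n_points, 6)),
            F=np.broadcast_to(np.eye(3), (n_points, 3, 3)).copy(),
            tangent6=np.broadcast_to(self.C6, (n_points, 6, 6)).copy(),
        )

    def update(self, state: MaterialPointState, dF: np.ndarray) -> None:
        D, W = kin.incremental_velocity_gradient(dF)
        state.stress6 += np.einsum("...ij,...j->...i", state.tangent6, tn.to_mandel(D))
        if self.corotational:
            t = tn.from_mandel(state.stress6)
            state.stress6 = tn.to_mandel(t + W @ t - t @ W)
        state.F = kin.update_deformation_gradient(state.F, dF - np.eye(3))


class AdventitiaMaterial:
    """Fiber-reinforced layer: matrix + n crimped collagen fiber families.

    Parameters mirror the tissue configuration: matrix modulus/Poisson
    ratio, collagen volume fraction (shared equally by the families),
    straight-fiber modulus ``E_f`` and Poisson ratio ``nu_c``, initial crimp
    ratio ``h0/ell0`` and fiber slenderness ``r_c/ell0``, and the initial
    Euler angles of the families.
    """

    def __init__(
        self,
        E_m: float,
        nu_m: float,
        f_c: float,
        E_f: float,
        nu_c: float,
        theta0: np.ndarray,
        phi0: np.ndarray,
        h0_over_ell0: float,
        rc_over_ell0: float,
        corotational: bool = False,
        crimp_measure: str = "arc",
    ):
        theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
        phi0 = np.atleast_1d(np.asarray(phi0, dtype=float))
        if theta0.shape != phi0.shape:
            raise ValueError("theta0 and phi0 must have the same length")
        if not 0.0 <= f_c < 1.0:
            raise ValueError("collagen volume fraction must lie in [0, 1)")
        self.matrix = mm.ElasticPhase(E_m, nu_m)
        self.Cm6 = self.matrix.stiffness_mandel
        self.Cm6_inv = np.linalg.inv(self.Cm6)
        self.E_f = float(E_f)
        self.nu_c = float(nu_c)
        self.theta0, self.phi0 = theta0, phi0
        self.nf = len(theta0)
        self.f_c = float(f_c)
        self.fractions = np.full(self.nf, f_c / self.nf) if self.nf else np.zeros(0)
        self.f_m = 1.0 - f_c
        self.recruitment = fib.FiberRecruitment(h0_over_ell0, rc_over_ell0)
        self.S6_loc, self.Pi_loc = mm.eshelby_cylinder_local(nu_m)
        self.corotational = corotational
        self.crimp_measure = crimp_measure
        self._drift_warned = False

    # -- state construction -------------------------------------------------

    def init_state(self, lrs0: np.ndarray) -> MaterialPointState:
        """Initial state for points with wall triads ``lrs0`` (N, 3, 3)."""
        lrs0 = np.asarray(lrs0, dtype=float)
        n = len(lrs0)
        triads = np.stack(
            [kin.frame_from_angles(self.phi0[i], self.theta0[i], lrs0)
             for i in range(self.nf)], axis=1,
        ) if self.nf else np.zeros((n, 0, 3, 3))
        eps = np.zeros((n, self.nf))
        k, e_ratio = self.recruitment.evaluate(eps, self.crimp_measure)
        state = MaterialPointState(
            stress6=np.zeros((n, 6)),
            F=np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
            tangent6=np.empty((n, 6, 6)),
            lrs=lrs0.copy(),
            triads=triads,
            eps_chord=eps,
            E_ratio=e_ratio,
            crimp_k=k,
            t_phase=np.zeros((n, self.nf + 1, 3, 3)),
        )
        self._rebuild(state)
        return state

    # -- micromechanical build ----------------------------------------------

    def _rebuild(self, state: MaterialPointState) -> None:
        """Concentration operators and homogenized tangent from current state."""
        if self.nf == 0:
            state.tangent6[:] = self.Cm6
            state.cache = {}
            return
        R = np.swapaxes(state.triads, -1, -2)        # columns c, pc, Nc
        Q = tn.mandel_rotation(R)                    # (N, nf, 6, 6)
        S6 = Q @ self.S6_loc @ np.swapaxes(Q, -1, -2)
        Ci6 = mm.isotropic_stiffness_mandel(state.E_ratio * self.E_f, self.nu_c)
        A_dil = np.linalg.inv(
            np.eye(6) + S6 @ self.Cm6_inv @ (Ci6 - self.Cm6)
        )
        A_fam, A_m = mm.mt_concentrations_mandel(A_dil, self.fractions, self.f_m)
        Pi_g = mm._rotate_pi(self.Pi_loc, R)
        Rop_fam = mm.spin_operators_mandel(Pi_g, self.Cm6, Ci6, A_fam)
        Rop_m = -np.einsum("i,nijkm->njkm", self.fractions, Rop_fam) / self.f_m
        state.tangent6 = mm.homogenized_tangent_mandel(
            self.Cm6, Ci6, A_fam, A_m, Rop_fam, Rop_m,
            state.t_phase[:, : self.nf], state.t_phase[:, self.nf],
            self.fractions, self.f_m,
        )
        state.cache = dict(A_fam=A_fam, A_m=A_m, Rop_fam=Rop_fam,
                           Rop_m=Rop_m, Ci6=Ci6)

    # -- the staggered update -----------------------------------------------

    def update(self, state: MaterialPointState, dF: np.ndarray) -> None:
        D, Wmac = kin.incremental_velocity_gradient(dF)
        D6 = tn.to_mandel(D)

        # 1. macroscopic stress, frozen tangent
        state.stress6 += np.einsum("nij,nj->ni", state.tangent6, D6)
        if self.corotational:
            t = tn.from_mandel(state.stress6)
            state.stress6 = tn.to_mandel(t + Wmac @ t - t @ Wmac)

        # 2. wall triad and deformation gradient
        state.lrs = kin.convect_local_frame(state.lrs, dF)
        state.F = kin.update_deformation_gradient(state.F, dF - np.eye(3))

        if self.nf == 0:
            return
        cache = state.cache

        # 3. phase fields from the step-n concentration operators
        d_fam6 = np.einsum("nfij,nj->nfi", cache["A_fam"], D6)
        w_fam = np.einsum("nfijm,nm->nfij", cache["Rop_fam"], D6)
        d_m6 = np.einsum("nij,nj->ni", cache["A_m"], D6)
        w_m = np.einsum("nijm,nm->nij", cache["Rop_m"], D6)
        if self.corotational:
            w_fam = w_fam + Wmac[:, None]
            w_m = w_m + Wmac
        d_fam = tn.from_mandel(d_fam6)

        # 4. phase stresses: material rate from the Jaumann constitutive rate,
        #    convection evaluated with the step-n phase stresses
        t_f = state.t_phase[:, : self.nf]
        t_f += (tn.from_mandel(np.einsum("nfij,nfj->nfi", cache["Ci6"], d_fam6))
                + w_fam @ t_f - t_f @ w_fam)
        t_m = state.t_phase[:, self.nf]
        t_m += (tn.from_mandel(np.einsum("ij,nj->ni", self.Cm6, d_m6))
                + w_m @ t_m - t_m @ w_m)

        # 5. chord strain increments along the pre-update fiber axes
        c = state.triads[..., 0, :]
        d_eps = np.einsum("nfi,nfij,nfj->nf", c, d_fam, c)

        # 6. fiber triads: normalized explicit update, then re-orthonormal-
        #    ization around the evolved fiber axis.  The raw update lets the
        #    three vectors drift out of orthogonality secularly (each line
        #    rotates at its own stretching-dependent rate), which would
        #    corrupt the rotation operators of the next RVE build; the fiber
        #    axis itself is kept exactly as evolved.
        evolved = kin.evolve_fiber_frame(state.triads, d_fam, w_fam)
        drift = kin.orthonormality_drift(evolved)
        if drift > 1e-3 and not self._drift_warned:
            warnings.warn(
                f"fiber-triad orthonormality drift reached {drift:.2e} within "
                "one increment (large load step)", RuntimeWarning, stacklevel=2,
            )
            self._drift_warned = True
        state.triads = kin.orthonormalize_triad(evolved)

        # 7. recruitment.  Deeply compressed (slack) fibers saturate: a soft
        #    crimped inclusion amplifies compressive strain and the affine
        #    period contraction would otherwise run away toward the
        #    non-physical chord collapse at eps = -1; below -0.9 the chord
        #    modulus is at its floor and the geometry bookkeeping is moot.
        state.eps_chord = np.maximum(state.eps_chord + d_eps, -0.9)
        state.crimp_k, state.E_ratio = self.recruitment.evaluate(
            state.eps_chord, self.crimp_measure
        )

        # 8. rebuild operators and tangent for step n+1
        self._rebuild(state)

    # -- outputs -------------------------------------------------------------

    def theta_angles(self, state: MaterialPointState) -> np.ndarray:
        """Per-family fiber angle to the axial direction (rad, in [0, pi/2]).

        Computed directly from the fiber axis, ``arccos |c . T|``; fibers
        are direction-less, so the angle is folded to [0, pi/2] (0 = axial,
        pi/2 = circumferential), the convention used for reporting.
        """
        c = state.triads[..., 0, :]
        t_ax = state.lrs[:, None, 1, :]
        return np.arccos(np.clip(np.abs(np.sum(c * t_ax, axis=-1)), 0.0, 1.0))

    def fiber_axial_stress(self, state: MaterialPointState) -> np.ndarray:
        """Along-fiber normal component of each family's phase stress, (N, nf)."""
        c = state.triads[..., 0, :]
        t_f = state.t_phase[:, : self.nf]
        return np.einsum("nfi,nfij,nfj->nf", c, t_f, c)


def material_point_driver(material, state: MaterialPointState, path):
    """Apply a homogeneous deformation path to a material-point batch.

    ``path`` is a sequence of incremental deformation gradients ``dF``
    (each (3,3) or (N,3,3)).  Returns the list of per-step state snapshots
    (macroscopic stress, tangent, and — for fiber materials — angles and
    chord-modulus ratios).  For a single finite element loaded by affine
    boundary displacements this trajectory coincides with the FE solution.
    """
    traj = []

    def snap():
        rec = {
            "stress": state.stress(),
            "F": state.F.copy(),
            "tangent6": state.tangent6.copy(),
        }
        if isinstance(material, AdventitiaMaterial) and material.nf:
            rec["theta"] = material.theta_angles(state)
            rec["E_ratio"] = state.E_ratio.copy()
            rec["fiber_stress"] = material.fiber_axial_stress(state)
        traj.append(rec)

    snap()
    for dF in path:
        dF = np.asarray(dF, dtype=float)
        if dF.ndim == 2:
            dF = np.broadcast_to(dF, (state.n_points, 3, 3))
        material.update(state, dF)
        snap()
    return traj
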