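"""Mean-field micromechanics of the adventitial RVE.

At every adventitial material point the tissue is a representative volume
element (RVE): an isotropic soft matrix (elastin network, ground substance,
fibroblasts) containing ``n`` families of infinitely long cylindrical
collagen inclusions.  Interactions between inclusions are treated with the
Mori-Tanaka scheme: each family is embedded, Eshelby-style, in the matrix
subjected to the matrix average strain rate.  The scheme yields

* per-family strain-rate concentration tensors ``A_i`` (``d_i = A_i : D``),
* per-family strain-rate-to-spin operators ``R_i`` (``w_i = R_i : D``) built
  from the antisymmetric part of the cylinder Eshelby problem, which drive
  the non-affine fiber rotation, and
* the homogenized hypoelastic tangent ``C_hom = sum_r f_r (C_r : A_r + W_r)``
  where ``W_r`` converts each phase's Jaumann stress rate to a material rate
  using the current phase stress and spin operator.

All heavy functions operate on Mandel 6x6 matrices and broadcast over
leading axes so a whole batch of Gauss points is updated at once; thin
object-level wrappers (``ElasticPhase``, ``RVEModel`` and the functions that
take them) expose single-RVE computations on full (3,3,3,3) tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import tensors as tn

__all__ = [
    "ElasticPhase",
    "FiberInclusion",
    "RVEModel",
    "isotropic_stiffness_mandel",
    "eshelby_cylinder",
    "eshelby_cylinder_local",
    "dilute_concentration",
    "dilute_concentration_mandel",
    "mt_concentrations",
    "mt_concentrations_mandel",
    "spin_concentration",
    "spin_operators_mandel",
    "homogenized_tangent",
    "homogenized_tangent_mandel",
    "phase_fields",
    "axis_completion",
    "jaumann_convection_mandel",
]

NU_MATRIX_MAX = 0.49   # Eshelby closed forms ill-conditioned toward nu = 1/2


def isotropic_stiffness_mandel(E, nu) -> np.ndarray:
    """Mandel 6x6 isotropic stiffness; broadcasts over the shape of ``E``."""
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(E <= 0):
        raise ValueError("Young's modulus must be > 0")
    if np.any(nu <= -1) or np.any(nu >= 0.5):
        raise ValueError("Poisson ratio must lie in (-1, 0.5)")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    shape = np.broadcast_shapes(lam.shape, mu.shape)
    out = np.zeros(shape + (6, 6))
    lam = np.broadcast_to(lam, shape)
    mu = np.broadcast_to(mu, shape)
    for a in range(3):
        for b in range(3):
            out[..., a, b] = lam + (2.0 * mu if a == b else 0.0)
    for a in range(3, 6):
        out[..., a, a] = 2.0 * mu
    return out


@dataclass(frozen=True)
class ElasticPhase:
    """Isotropic hypoelastic phase (modulus and Poisson ratio)."""

    E: float
    nu: float

    def __post_init__(self):
        isotropic_stiffness_mandel(self.E, self.nu)  # validation

    @property
    def stiffness_mandel(self) -> np.ndarray:
        return isotropic_stiffness_mandel(self.E, self.nu)

    @property
    def stiffness(self) -> np.ndarray:
        return tn.from_mandel4(self.stiffness_mandel)


@dataclass(frozen=True)
class FiberInclusion:
    """One collagen fiber family: phase, axis and volume fraction."""

    phase: ElasticPhase
    axis: np.ndarray
    volume_fraction: float

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-8:
            raise ValueError("fiber axis must be a unit vector")
        object.__setattr__(self, "axis", a)
        if not 0.0 <= self.volume_fraction < 1.0:
            raise ValueError("volume fraction must lie in [0, 1)")


@dataclass(frozen=True)
class RVEModel:
    """Matrix plus fiber-family inclusions; ``f_m = 1 - sum(f_i)``."""

    matrix: ElasticPhase
    inclusions: Sequence[FiberInclusion] = field(default_factory=tuple)

    def __post_init__(self):
        if self.f_matrix <= 0.0:
            raise ValueError("matrix volume fraction must be positive")

    @property
    def f_matrix(self) -> float:
        return 1.0 - sum(i.volume_fraction for i in self.inclusions)


# ----------------------------------------------------------------------
# Eshelby problem for the infinite circular cylinder
# ----------------------------------------------------------------------

# unit-circle quadrature in the transverse plane; the isotropic integrands
# are trigonometric polynomials of low degree, so a 64-point trapezoid rule
# on the periodic interval is exact to machine precision.
_PHI = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)


def eshelby_cylinder_local(nu_m: float):
    """Eshelby and rotation operators of an infinite cylinder along e1.

    Returns ``(S6, Pi)`` where ``S6`` is the Mandel matrix of the classical
    Eshelby tensor and ``Pi`` is a (3,3,6) array mapping a Mandel eigenstrain
    vector to the (antisymmetric) inclusion rotation.  Both are obtained from
    the line integral of the Green operator over transverse directions
    ``n = (0, cos p, sin p)``:

        T_ijkl = <N_ik(n) n_j n_l>_p ,  N = (C_m . n . n)^-1

    with ``S = sym_(ij) T : C_m`` and ``Pi = asym_(ij) T : C_m``.
    """
    if not -1.0 < nu_m < 0.5:
        raise ValueError("matrix Poisson ratio must lie in (-1, 0.5)")
    if nu_m > NU_MATRIX_MAX:
        raise ValueError(
            f"matrix Poisson ratio capped at {NU_MATRIX_MAX} to keep the "
            "cylinder Eshelby operators well-conditioned"
        )
    # with E = 1: N depends on C_m only through nu (homogeneous of degree -1,
    # and T : C_m is degree 0), so unit modulus suffices.
    lam = nu_m / ((1.0 + nu_m) * (1.0 - 2.0 * nu_m))
    mu = 1.0 / (2.0 * (1.0 + nu_m))
    n = np.stack([np.zeros_like(_PHI), np.cos(_PHI), np.sin(_PHI)], axis=-1)
    nn = np.einsum("pi,pj->pij", n, n)
    N = (np.eye(3) - (lam + mu) / (lam + 2.0 * mu) * nn) / mu
    T = np.einsum("pik,pj,pl->ijkl", N, n, n) / len(_PHI)
    T = 0.5 * (T + np.swapaxes(T, -1, -2))          # symmetrize (k,l)
    Cm = tn.from_mandel4(isotropic_stiffness_mandel(1.0, nu_m))
    TC = np.einsum("ijmn,mnkl->ijkl", T, Cm)
    S = 0.5 * (TC + np.swapaxes(TC, 0, 1))
    A = 0.5 * (TC - np.swapaxes(TC, 0, 1))
    S6 = tn.to_mandel4(S)
    # fold the antisymmetric part into a (3,3,6) map on Mandel strain vectors
    Pi = np.zeros((3, 3, 6))
    w = np.array([1.0, 1.0, 1.0, np.sqrt(2), np.sqrt(2), np.sqrt(2)])
    for m, (k, l) in enumerate(tn.MANDEL_PAIRS):
        Pi[:, :, m] = (A[:, :, k, l] + A[:, :, l, k]) / w[m]
    return S6, Pi


def axis_completion(axis: np.ndarray) -> np.ndarray:
    """Deterministic proper-orthogonal matrix with first column ``axis``."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    helper = np.zeros(3)
    helper[np.argmin(np.abs(a))] = 1.0
    b = np.cross(a, helper)
    b /= np.linalg.norm(b)
    c = np.cross(a, b)
    return np.column_stack([a, b, c])


def eshelby_cylinder(nu_m: float, axis: np.ndarray) -> np.ndarray:
    """Eshelby tensor of an infinite circular cylinder, global basis.

    Computed in the cylinder frame from the classical closed form (via the
    transverse Green-operator integral) and rotated so that the cylinder
    axis coincides with ``axis``.  All components contracted with the axis
    direction alone vanish (``S_aaaa = 0``).
    """
    S6, _ = eshelby_cylinder_local(nu_m)
    R = axis_completion(axis)
    Q = tn.mandel_rotation(R)
    return tn.from_mandel4(Q @ S6 @ Q.T)


# ----------------------------------------------------------------------
# Concentration tensors (batched Mandel kernels + object API)
# ----------------------------------------------------------------------

def dilute_concentration_mandel(S6, Cm6, Ci6) -> np.ndarray:
    """Dilute strain(-rate) concentration ``[I + S : Cm^-1 : (Ci - Cm)]^-1``."""
    bracket = np.eye(6) + S6 @ np.linalg.inv(Cm6) @ (Ci6 - Cm6)
    cond = np.linalg.cond(bracket)
    if np.any(~np.isfinite(cond)) or np.any(cond > 1e12):
        raise np.linalg.LinAlgError(
            "dilute concentration bracket is singular (extreme phase contrast)"
        )
    return np.linalg.inv(bracket)


def dilute_concentration(S, C_m, C_i) -> np.ndarray:
    """Object-level dilute concentration on full (3,3,3,3) tensors."""
    A6 = dilute_concentration_mandel(
        tn.to_mandel4(S), tn.to_mandel4(C_m), tn.to_mandel4(C_i)
    )
    return tn.from_mandel4(A6)


def mt_concentrations_mandel(A_dil, fractions, f_m):
    """Mori-Tanaka concentrations from dilute ones.

    Parameters
    ----------
    A_dil : (..., nf, 6, 6) dilute concentration per family
    fractions : (nf,) family volume fractions
    f_m : matrix volume fraction

    Returns ``(A_fam (...,nf,6,6), A_matrix (...,6,6))`` with
    ``f_m A_matrix + sum_i f_i A_fam_i = I``.
    """
    fractions = np.asarray(fractions, dtype=float)
    mean = f_m * np.eye(6) + np.einsum("i,...ijk->...jk", fractions, A_dil)
    A_m = np.linalg.inv(mean)
    A_fam = A_dil @ A_m[..., None, :, :]
    return A_fam, A_m


def _rve_mandel_parts(rve: RVEModel):
    Cm6 = rve.matrix.stiffness_mandel
    S6_loc, Pi_loc = eshelby_cylinder_local(rve.matrix.nu)
    A_dil, Ci6s, Rots = [], [], []
    for inc in rve.inclusions:
        R = axis_completion(inc.axis)
        Q = tn.mandel_rotation(R)
        S6 = Q @ S6_loc @ Q.T
        Ci6 = inc.phase.stiffness_mandel
        A_dil.append(dilute_concentration_mandel(S6, Cm6, Ci6))
        Ci6s.append(Ci6)
        Rots.append(R)
    fr = np.array([inc.volume_fraction for inc in rve.inclusions])
    A_fam, A_m = mt_concentrations_mandel(np.array(A_dil).reshape(-1, 6, 6)
                                          if A_dil else np.zeros((0, 6, 6)),
                                          fr, rve.f_matrix)
    return Cm6, Pi_loc, Rots, np.array(Ci6s).reshape(-1, 6, 6), A_fam, A_m, fr


def mt_concentrations(rve: RVEModel) -> dict:
    """Mori-Tanaka strain-rate concentration tensors, full-tensor output.

    Returns a dict with key ``"matrix"`` and one integer key per fiber
    family; values are (3,3,3,3) tensors satisfying the strain-rate average
    rule ``sum_r f_r A_r = I``.
    """
    _, _, _, _, A_fam, A_m, _ = _rve_mandel_parts(rve)
    out = {"matrix": tn.from_mandel4(A_m)}
    for i in range(len(rve.inclusions)):
        out[i] = tn.from_mandel4(A_fam[i])
    return out


def _rotate_pi(Pi_loc: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Express the local (3,3,6) rotation operator in the global basis."""
    Q = tn.mandel_rotation(R)
    return np.einsum("...ip,...jq,pqn,...mn->...ijm", R, R, Pi_loc, Q)


def spin_operators_mandel(Pi_glob, Cm6, Ci6, A_fam):
    """Strain-rate-to-spin operators ``R_i`` of each family, (...,nf,3,3,6).

    ``w_i = R_i : D`` with ``R_i = -Pi : Cm^-1 : (Ci - Cm) : A_i^MT``: the
    equivalent eigenstrain of the Eshelby equivalence condition is
    ``eps* = -Cm^-1 : (Ci - Cm) : eps_i``, and ``Pi`` maps it to the
    inclusion rotation.  Identical phases therefore give zero spin.
    """
    M = np.linalg.inv(Cm6) @ (Ci6 - Cm6) @ A_fam
    return -np.einsum("...ijn,...nm->...ijm", Pi_glob, M)


def spin_concentration(rve: RVEModel, family: int | FiberInclusion) -> np.ndarray:
    """Spin operator of one family as a (3,3,6) map on Mandel strain vectors."""
    if isinstance(family, FiberInclusion):
        family = list(rve.inclusions).index(family)
    Cm6, Pi_loc, Rots, Ci6s, A_fam, _, _ = _rve_mandel_parts(rve)
    Pi_g = _rotate_pi(Pi_loc, Rots[family])
    return spin_operators_mandel(Pi_g, Cm6, Ci6s[family], A_fam[family])


def phase_fields(rve: RVEModel, D: np.ndarray) -> dict:
    """Average strain rate and spin of every phase for a macroscopic ``D``.

    Returns ``{key: (d, w)}`` with symmetric ``d`` and antisymmetric ``w``;
    the matrix spin balances the family spins so the volume average of all
    phase spins vanishes (a pure strain rate is imposed on the RVE boundary).
    """
    D = np.asarray(D, dtype=float)
    if np.max(np.abs(D - D.T)) > 1e-10 * max(np.max(np.abs(D)), 1.0):
        raise ValueError("macroscopic strain rate must be symmetric")
    Cm6, Pi_loc, Rots, Ci6s, A_fam, A_m, fr = _rve_mandel_parts(rve)
    D6 = tn.to_mandel(D)
    out = {"matrix": None}
    w_sum = np.zeros((3, 3))
    for i in range(len(rve.inclusions)):
        Pi_g = _rotate_pi(Pi_loc, Rots[i])
        Rop = spin_operators_mandel(Pi_g, Cm6, Ci6s[i], A_fam[i])
        d = tn.from_mandel(A_fam[i] @ D6)
        w = np.einsum("ijm,m->ij", Rop, D6)
        out[i] = (d, w)
        w_sum += fr[i] * w
    d_m = tn.from_mandel(A_m @ D6)
    w_m = -w_sum / rve.f_matrix if len(rve.inclusions) else np.zeros((3, 3))
    out["matrix"] = (d_m, w_m)
    return out


# ----------------------------------------------------------------------
# Homogenized tangent
# ----------------------------------------------------------------------

def jaumann_convection_mandel(Rop, t):
    """Mandel 6x6 operator W with ``W : D = w.t - t.w``, ``w = Rop : D``.

    This is the spin-convection term converting a phase's Jaumann stress
    rate into a material rate inside the homogenized tangent.  ``Rop`` is
    (...,3,3,6), ``t`` the (...,3,3) phase Cauchy stress.
    """
    W4 = np.einsum("...ipm,...pj->...ijm", Rop, t) - np.einsum(
        "...ip,...pjm->...ijm", t, Rop
    )
    # W4 is symmetric in (i, j); fold rows into Mandel form
    out = np.empty(W4.shape[:-3] + (6, 6))
    w = np.array([1.0, 1.0, 1.0, np.sqrt(2), np.sqrt(2), np.sqrt(2)])
    for m, (i, j) in enumerate(tn.MANDEL_PAIRS):
        out[..., m, :] = w[m] * W4[..., i, j, :]
    return out


def homogenized_tangent_mandel(Cm6, Ci6, A_fam, A_m, Rop_fam, Rop_m,
                               t_fam, t_m, fractions, f_m):
    """Homogenized tangent ``sum_r f_r (C_r : A_r + W_r)`` in Mandel form."""
    fractions = np.asarray(fractions, dtype=float)
    C = f_m * (Cm6 @ A_m + jaumann_convection_mandel(Rop_m, t_m))
    terms = Ci6 @ A_fam + jaumann_convection_mandel(Rop_fam, t_fam)
    C = C + np.einsum("i,...ijk->...jk", fractions, terms)
    return C


def homogenized_tangent(rve: RVEModel, phase_stresses: dict) -> np.ndarray:
    """Homogenized hypoelastic tangent of the RVE, full-tensor output.

    ``phase_stresses`` maps ``"matrix"`` and each family index to the phase
    Cauchy stress (3,3); all keys must be present.  At zero phase stress the
    tangent reduces to the plain stress-average composition
    ``sum_r f_r C_r : A_r`` (major-symmetric for symmetric microgeometry).
    """
    Cm6, Pi_loc, Rots, Ci6s, A_fam, A_m, fr = _rve_mandel_parts(rve)
    nf = len(rve.inclusions)
    missing = [k for k in ["matrix", *range(nf)] if k not in phase_stresses]
    if missing:
        raise ValueError(f"missing phase stresses for {missing}")
    if nf == 0:
        return tn.from_mandel4(Cm6)
    Rop_fam = np.stack([
        spin_operators_mandel(_rotate_pi(Pi_loc, Rots[i]), Cm6, Ci6s[i], A_fam[i])
        for i in range(nf)
    ])
    Rop_m = -np.einsum("i,ijkm->jkm", fr, Rop_fam) / rve.f_matrix
    t_fam = np.stack([np.asarray(phase_stresses[i], dtype=float) for i in range(nf)])
    t_m = np.asarray(phase_stresses["matrix"], dtype=float)
    C6 = homogenized_tangent_mandel(Cm6, np.array(Ci6s), A_fam, A_m,
                                    Rop_fam, Rop_m, t_fam, t_m, fr, rve.f_matrix)
    return tn.from_mandel4(C6)
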