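"""Frame kinematics: wall triad convection, fiber triads and Euler angles.

Two orthonormal triads live at every adventitial material point, both stored
in the global Cartesian basis:

* the local reference system (K, T, N) of the wall — circumferential, axial
  and radial directions — which convects with the macroscopic incremental
  deformation gradient (K follows the deformation, T is re-orthogonalized by
  Gram-Schmidt, N closes the right-handed triad);
* one fiber triad (c, perp_c, N_c) per collagen family, related to the wall
  triad through the Euler angles (phi, theta):

      c      = (cos phi cos theta) N + (sin phi cos theta) T - (sin theta) K
      perp_c = -(sin phi) N + (cos phi) T
      N_c    = (cos phi sin theta) N + (sin phi sin theta) T + (cos theta) K

  so theta = 0 puts the fiber along the axial direction (when phi = pi/2)
  and theta = pi/2 along the circumferential one.  Fiber triads evolve with
  the per-family micro velocity gradient ``d + w`` through the normalized
  explicit update; the triad is deliberately NOT re-orthogonalized (the
  algorithm is followed literally), but orthogonality drift is monitored.

All functions broadcast over leading batch axes.  Triads are stored as
(..., 3, 3) arrays whose ROWS are the vectors: ``lrs[..., 0, :] = K`` etc.,
``triad[..., 0, :] = c``, ``triad[..., 1, :] = perp_c``, ``triad[..., 2, :] = N_c``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "frame_from_angles",
    "angles_from_frame",
    "evolve_fiber_frame",
    "update_deformation_gradient",
    "convect_local_frame",
    "orthonormality_drift",
    "incremental_velocity_gradient",
]

_ORTHO_WARN = 1e-3


def frame_from_angles(phi, theta, lrs: np.ndarray) -> np.ndarray:
    """Fiber triad (rows c, perp_c, N_c) from Euler angles and wall triad."""
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    K, T, N = lrs[..., 0, :], lrs[..., 1, :], lrs[..., 2, :]
    cp, sp = np.cos(phi)[..., None], np.sin(phi)[..., None]
    ct, st = np.cos(theta)[..., None], np.sin(theta)[..., None]
    c = cp * ct * N + sp * ct * T - st * K
    perp = -sp * N + cp * T
    nc = cp * st * N + sp * st * T + ct * K
    return np.stack([c, perp, nc], axis=-2)


def angles_from_frame(triad: np.ndarray, lrs: np.ndarray):
    """Euler angles (phi, theta) of a fiber triad relative to the wall triad.

    phi is extracted from ``perp_c . T = cos phi`` with the quadrant branch
    decided by the sign of ``-perp_c . N = sin phi`` (two-branch formula,
    phi in [0, 2 pi)); theta from ``N_c . K = cos theta``, theta in [0, pi].
    Round-trips with :func:`frame_from_angles`.
    """
    K, T, N = lrs[..., 0, :], lrs[..., 1, :], lrs[..., 2, :]
    perp, nc = triad[..., 1, :], triad[..., 2, :]
    cos_phi = np.clip(np.sum(perp * T, axis=-1), -1.0, 1.0)
    sin_phi = -np.sum(perp * N, axis=-1)
    phi = np.arccos(cos_phi)
    phi = np.where(sin_phi >= 0.0, phi, 2.0 * np.pi - phi)
    cos_theta = np.clip(np.sum(nc * K, axis=-1), -1.0, 1.0)
    theta = np.arccos(cos_theta)
    return phi, theta


def evolve_fiber_frame(triad: np.ndarray, d: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Explicit normalized update of a fiber triad.

    Each triad vector ``a`` becomes ``(a + (d + w) . a) / ||a + (d + w) . a||``
    with ``d`` the family strain-rate increment (symmetric) and ``w`` its spin
    (antisymmetric); increments are per-step quantities (unit pseudo-time).
    """
    L = np.asarray(d, dtype=float) + np.asarray(omega, dtype=float)
    new = triad + np.einsum("...ij,...vj->...vi", L, triad)
    norms = np.linalg.norm(new, axis=-1, keepdims=True)
    if np.any(norms < 1e-12):
        raise FloatingPointError("fiber triad vector collapsed during update")
    return new / norms


def orthonormalize_triad(triad: np.ndarray) -> np.ndarray:
    """Re-orthonormalize a fiber triad around its (exact) first vector.

    The fiber axis ``c`` is kept as evolved (it is the physical direction
    entering the RVE definition and the chord-strain measure); ``perp_c``
    is Gram-Schmidt-projected and ``N_c`` rebuilt by a cross product with
    the sign chosen to stay close to the evolved ``N_c``.  The remaining
    rotation gauge about ``c`` does not affect the micromechanics, which is
    transversely isotropic about the fiber axis.
    """
    c = triad[..., 0, :]
    c = c / np.linalg.norm(c, axis=-1, keepdims=True)
    p = triad[..., 1, :]
    p = p - np.sum(p * c, axis=-1, keepdims=True) * c
    norms = np.linalg.norm(p, axis=-1, keepdims=True)
    if np.any(norms < 1e-10):
        raise FloatingPointError("degenerate fiber triad (perp_c parallel to c)")
    p = p / norms
    n = np.cross(c, p)
    sign = np.sign(np.sum(n * triad[..., 2, :], axis=-1, keepdims=True))
    sign = np.where(sign == 0.0, 1.0, sign)
    return np.stack([c, p, sign * n], axis=-2)


def orthonormality_drift(triad: np.ndarray) -> float:
    """Max deviation of the triad Gram matrix from identity (monitoring)."""
    g = np.einsum("...vi,...wi->...vw", triad, triad)
    return float(np.max(np.abs(g - np.eye(3))))


def update_deformation_gradient(F: np.ndarray, dU_gradient: np.ndarray) -> np.ndarray:
    """Accumulate ``F <- (I + grad dU) . F``; rejects element inversion."""
    dF = np.eye(3) + np.asarray(dU_gradient, dtype=float)
    if np.any(np.linalg.det(dF) <= 0.0):
        raise FloatingPointError("non-positive det of incremental gradient (inversion)")
    return np.einsum("...ij,...jk->...ik", dF, F)


def incremental_velocity_gradient(dF: np.ndarray):
    """Strain-rate and spin increments of an incremental deformation gradient.

    The incremental velocity gradient is ``L = dF - I`` (unit pseudo-time
    step, so L -> 0 at rest); returns ``(D, W)`` its symmetric and
    antisymmetric parts.  This isolates the interpretation of the
    macroscopic rate driving the RVE.
    """
    L = np.asarray(dF, dtype=float) - np.eye(3)
    return 0.5 * (L + np.swapaxes(L, -1, -2)), 0.5 * (L - np.swapaxes(L, -1, -2))


def convect_local_frame(lrs: np.ndarray, dF: np.ndarray) -> np.ndarray:
    """Convect the wall triad with an incremental deformation gradient.

    K follows the deformation and is renormalized; T is convected, then
    Gram-Schmidt-orthogonalized against the new K; N = K x T closes the
    right-handed triad.  A rigid rotation rotates the triad exactly.
    """
    dF = np.asarray(dF, dtype=float)
    if np.any(np.linalg.det(dF) <= 0.0):
        raise FloatingPointError("non-positive det of incremental gradient")
    K = np.einsum("...ij,...j->...i", dF, lrs[..., 0, :])
    K = K / np.linalg.norm(K, axis=-1, keepdims=True)
    Tbar = np.einsum("...ij,...j->...i", dF, lrs[..., 1, :])
    Tbar = Tbar / np.linalg.norm(Tbar, axis=-1, keepdims=True)
    T = Tbar - np.sum(Tbar * K, axis=-1, keepdims=True) * K
    nT = np.linalg.norm(T, axis=-1, keepdims=True)
    if np.any(nT < 1e-10):
        raise FloatingPointError("degenerate wall triad: K parallel to convected T")
    T = T / nT
    N = np.cross(K, T)
    return np.stack([K, T, N], axis=-2)
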