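"""Fourth-order tensor algebra in Mandel (orthonormal-basis) notation.

Conventions used throughout the package
---------------------------------------
* Second-order tensors are ``(..., 3, 3)`` numpy arrays in a fixed global
  Cartesian basis.  Local frames (wall triad, fiber triads) are explicit
  rotation operators applied on demand.
* Symmetric second-order tensors have a 6-component Mandel vector view::

      [a11, a22, a33, sqrt(2) a23, sqrt(2) a13, sqrt(2) a12]

  so the Euclidean inner product of two Mandel vectors equals the full
  double contraction ``a : b``.
* Minor-symmetric fourth-order tensors have a ``(..., 6, 6)`` Mandel matrix
  view in which double contraction and inversion coincide with ordinary
  matrix products and inverses (no Voigt bookkeeping factors).

All functions broadcast over leading axes, which is what makes the
per-Gauss-point micromechanics update affordable in pure numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MANDEL_PAIRS",
    "to_mandel",
    "from_mandel",
    "to_mandel4",
    "from_mandel4",
    "mandel_rotation",
    "rotate4",
    "sym",
    "skew",
    "identity4_sym",
    "jaumann_to_material_rate",
    "is_minor_symmetric",
    "check_rotation",
]

#: (i, j) index pairs of the Mandel ordering.
MANDEL_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))

_SQRT2 = np.sqrt(2.0)
_W = np.array([1.0, 1.0, 1.0, _SQRT2, _SQRT2, _SQRT2])


def sym(a: np.ndarray) -> np.ndarray:
    """Symmetric part of a (...,3,3) tensor."""
    return 0.5 * (a + np.swapaxes(a, -1, -2))


def skew(a: np.ndarray) -> np.ndarray:
    """Antisymmetric part of a (...,3,3) tensor."""
    return 0.5 * (a - np.swapaxes(a, -1, -2))


def to_mandel(a: np.ndarray) -> np.ndarray:
    """Symmetric (...,3,3) tensor -> (...,6) Mandel vector."""
    a = np.asarray(a, dtype=float)
    out = np.empty(a.shape[:-2] + (6,))
    for m, (i, j) in enumerate(MANDEL_PAIRS):
        out[..., m] = _W[m] * a[..., i, j]
    return out


def from_mandel(v: np.ndarray) -> np.ndarray:
    """(...,6) Mandel vector -> symmetric (...,3,3) tensor."""
    v = np.asarray(v, dtype=float)
    out = np.zeros(v.shape[:-1] + (3, 3))
    for m, (i, j) in enumerate(MANDEL_PAIRS):
        out[..., i, j] = v[..., m] / _W[m]
        out[..., j, i] = v[..., m] / _W[m]
    return out


def is_minor_symmetric(t4: np.ndarray, tol: float = 1e-9) -> bool:
    """True if a (...,3,3,3,3) tensor has both minor symmetries."""
    t4 = np.asarray(t4)
    scale = max(np.max(np.abs(t4)), 1.0)
    return bool(
        np.max(np.abs(t4 - np.swapaxes(t4, -4, -3))) <= tol * scale
        and np.max(np.abs(t4 - np.swapaxes(t4, -2, -1))) <= tol * scale
    )


def to_mandel4(t4: np.ndarray, check: bool = True) -> np.ndarray:
    """Minor-symmetric (...,3,3,3,3) tensor -> (...,6,6) Mandel matrix.

    Raises ``ValueError`` when the input lacks a minor symmetry (the Mandel
    matrix would silently drop components otherwise).
    """
    t4 = np.asarray(t4, dtype=float)
    if check and not is_minor_symmetric(t4):
        raise ValueError("tensor lacks minor symmetry; Mandel view undefined")
    out = np.empty(t4.shape[:-4] + (6, 6))
    for m, (i, j) in enumerate(MANDEL_PAIRS):
        for n, (k, l) in enumerate(MANDEL_PAIRS):
            out[..., m, n] = _W[m] * _W[n] * t4[..., i, j, k, l]
    return out


def from_mandel4(m66: np.ndarray) -> np.ndarray:
    """(...,6,6) Mandel matrix -> minor-symmetric (...,3,3,3,3) tensor."""
    m66 = np.asarray(m66, dtype=float)
    out = np.zeros(m66.shape[:-2] + (3, 3, 3, 3))
    for m, (i, j) in enumerate(MANDEL_PAIRS):
        for n, (k, l) in enumerate(MANDEL_PAIRS):
            val = m66[..., m, n] / (_W[m] * _W[n])
            out[..., i, j, k, l] = val
            out[..., j, i, k, l] = val
            out[..., i, j, l, k] = val
            out[..., j, i, l, k] = val
    return out


def identity4_sym() -> np.ndarray:
    """6x6 Mandel matrix of the identity on symmetric second-order tensors."""
    return np.eye(6)


def check_rotation(r: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Validate a proper-orthogonal (...,3,3) matrix; returns it unchanged."""
    r = np.asarray(r, dtype=float)
    rtr = np.einsum("...ki,...kj->...ij", r, r)
    if np.max(np.abs(rtr - np.eye(3))) > tol:
        raise ValueError("matrix is not orthogonal")
    if np.max(np.abs(np.linalg.det(r) - 1.0)) > tol:
        raise ValueError("matrix is not proper (det != +1)")
    return r


def mandel_rotation(r: np.ndarray) -> np.ndarray:
    """Mandel 6x6 matrix Q of the basis rotation induced by ``r``.

    For a symmetric tensor ``a`` with Mandel vector ``v``, the rotated tensor
    ``r a r^T`` has Mandel vector ``Q v``; for a minor-symmetric fourth-order
    tensor ``M`` the rotated Mandel matrix is ``Q M Q^T``.  Q is orthogonal.
    """
    r = np.asarray(r, dtype=float)
    big = np.einsum("...ik,...jl->...ijkl", r, r)
    # minor-symmetrize in the last index pair: acts on symmetric tensors only
    big = 0.5 * (big + np.swapaxes(big, -1, -2))
    return to_mandel4(big, check=False)


def rotate4(t4: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Rotate a (...,3,3,3,3) tensor: (r o t4)_ijkl = r_ip r_jq r_kr r_ls t4_pqrs."""
    check_rotation(r)
    return np.einsum("...ip,...jq,...kr,...ls,...pqrs->...ijkl", r, r, r, r, t4)


def jaumann_to_material_rate(
    t: np.ndarray, spin: np.ndarray, objective_rate: np.ndarray
) -> np.ndarray:
    """Material stress rate from a Jaumann (corotational) rate.

    The Jaumann rate is defined as ``t_obj = t_dot + t.w - w.t`` with ``w``
    the spin; this inverts it: ``t_dot = t_obj - t.w + w.t``.  Spherical
    stresses commute with any spin, so they pick up no convection.
    """
    t = np.asarray(t, dtype=float)
    spin = np.asarray(spin, dtype=float)
    scale = max(np.max(np.abs(spin)), 1.0)
    if np.max(np.abs(spin + np.swapaxes(spin, -1, -2))) > 1e-10 * scale:
        raise ValueError("spin must be antisymmetric")
    return (
        np.asarray(objective_rate, dtype=float)
        - np.einsum("...ij,...jk->...ik", t, spin)
        + np.einsum("...ij,...jk->...ik", spin, t)
    )
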