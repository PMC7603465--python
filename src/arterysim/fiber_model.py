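"""Crimped collagen fiber model.

A collagen fiber is modeled as a planar homogeneous beam of circular cross
section (radius ``r_c``) whose centerline is a sinusoid
``g(s) = h sin(s / ell)`` with amplitude ``h`` and period parameter ``ell``
(one geometric period spans ``s in [0, 2 pi ell]``).  The slope of the
centerline is ``alpha(s) = (h / ell) cos(s / ell)`` (small-slope beam
convention: ``alpha`` is used directly as the argument of the cosines).

The apparent axial stiffness measured along the chord of one period is the
chord modulus

    E_c = E_f * I_c <cos a> / (I_c <cos^2 a> + A_c <g^2>)

with ``A_c = pi r_c^2``, ``I_c = pi r_c^4 / 4`` and ``< . >`` the curvilinear
average over one period.  A straight fiber (h = 0) has ``E_c = E_f``; a
strongly crimped one is orders of magnitude softer because bending, not
stretching, accommodates the chord elongation.

De-crimping law
---------------
The evolution of ``(h, ell)`` with the accumulated along-the-chord strain
``eps`` is kinematic: the period stretches affinely, ``ell = ell0 (1+eps)``,
and the amplitude follows from conservation of the (inextensible) centerline
arc length over one period.  When the stretched chord reaches the initial
arc length the fiber is fully recruited: ``h = 0`` and ``E_c = E_f``
thereafter.  Because only the ratios ``h/ell`` and ``r_c/ell`` enter the
chord modulus, recruitment is fully characterized by the initial crimp ratio
``k0 = h0/ell0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "CrimpGeometry",
    "CrimpedFiberState",
    "curvilinear_average",
    "chord_modulus",
    "chord_modulus_ratio",
    "flat_measure_closed_forms",
    "arc_length",
    "chord_strain_increment",
    "update_crimp",
    "FiberRecruitment",
]


@dataclass(frozen=True)
class CrimpGeometry:
    """Sinusoidal crimp geometry; lengths in consistent units (micrometers)."""

    h: float        # amplitude
    ell: float      # period parameter (period length along s is 2 pi ell)
    r_c: float      # fiber cross-section radius

    def __post_init__(self):
        if self.h < 0:
            raise ValueError("amplitude h must be >= 0")
        if self.ell <= 0 or self.r_c <= 0:
            raise ValueError("ell and r_c must be > 0")

    @property
    def k(self) -> float:
        """Crimp ratio h/ell."""
        return self.h / self.ell

    @property
    def area(self) -> float:
        return np.pi * self.r_c**2

    @property
    def inertia(self) -> float:
        return np.pi * self.r_c**4 / 4.0

    def g(self, s):
        return self.h * np.sin(np.asarray(s) / self.ell)

    def slope(self, s):
        """Centerline slope alpha(s) = (h/ell) cos(s/ell)."""
        return self.k * np.cos(np.asarray(s) / self.ell)


def curvilinear_average(
    fn: Callable[[np.ndarray], np.ndarray],
    geom: CrimpGeometry,
    measure: str = "arc",
) -> float:
    """Average of ``fn(s)`` over one crimp period.

    With ``measure='arc'`` (default, the literal curvilinear average along
    the centerline) the weight is the arc element
    ``dL = sqrt(1 + g'(s)^2) ds``; with ``measure='flat'`` the plain ``ds``
    measure is used (sensitivity variant; it admits Bessel closed forms).
    """
    period = 2.0 * np.pi * geom.ell
    if measure == "arc":
        w = lambda s: np.sqrt(1.0 + geom.slope(s) ** 2)
    elif measure == "flat":
        w = lambda s: np.ones_like(np.asarray(s, dtype=float))
    else:
        raise ValueError(f"unknown measure {measure!r}")

    num, _ = integrate.quad(lambda s: fn(s) * w(s), 0.0, period,
                            epsabs=0.0, epsrel=1e-10, limit=200)
    den, _ = integrate.quad(w, 0.0, period, epsabs=0.0, epsrel=1e-10, limit=200)
    if not np.isfinite(num) or not np.isfinite(den):
        raise ValueError("non-finite integrand in curvilinear average")
    return num / den


# 64-point Gauss-Legendre rule on [0, 2 pi]; the integrands are smooth and
# periodic, so this is far below 1e-10 relative error for k <= 1.
_GL_U, _GL_W = np.polynomial.legendre.leggauss(64)
_GL_U = np.pi * (_GL_U + 1.0)          # map [-1,1] -> [0, 2 pi]
_GL_W = np.pi * _GL_W


def _averages(k, measure: str = "arc"):
    """Vectorized curvilinear averages entering the chord modulus.

    Returns ``(<cos a>, <cos^2 a>, <sin^2 u>)`` for crimp ratio(s) ``k``,
    where ``<g^2> = h^2 <sin^2 u>``.  Broadcasts over the shape of ``k``.
    """
    k = np.asarray(k, dtype=float)[..., None]
    alpha = k * np.cos(_GL_U)
    if measure == "arc":
        w = np.sqrt(1.0 + alpha**2) * _GL_W
    else:
        w = np.broadcast_to(_GL_W, alpha.shape)
    den = np.sum(w, axis=-1)
    cos_a = np.sum(np.cos(alpha) * w, axis=-1) / den
    cos2_a = np.sum(np.cos(alpha) ** 2 * w, axis=-1) / den
    sin2_u = np.sum(np.sin(_GL_U) ** 2 * w, axis=-1) / den
    return cos_a, cos2_a, sin2_u


def chord_modulus_ratio(k, r_over_ell, measure: str = "arc"):
    """``E_c / E_f`` as a function of crimp ratio and slenderness (vectorized)."""
    k = np.asarray(k, dtype=float)
    r = np.asarray(r_over_ell, dtype=float)
    cos_a, cos2_a, sin2_u = _averages(k, measure)
    g2 = k**2 * sin2_u                      # <g^2> / ell^2
    quarter_r2 = r**2 / 4.0                 # I_c / (A_c ell^2)
    ratio = quarter_r2 * cos_a / (quarter_r2 * cos2_a + g2)
    return np.where(k == 0.0, 1.0, ratio)


def chord_modulus(E_f: float, geom: CrimpGeometry, measure: str = "arc") -> float:
    """Chord elastic modulus of the crimped fiber (same units as ``E_f``)."""
    if E_f <= 0:
        raise ValueError("E_f must be > 0")
    return float(E_f * chord_modulus_ratio(geom.k, geom.r_c / geom.ell, measure))


def flat_measure_closed_forms(k):
    """Bessel closed forms of the flat-measure averages.

    ``<cos a> = J0(k)``, ``<cos^2 a> = (1 + J0(2k))/2``, ``<g^2>/h^2 = 1/2``.
    Used as an independent cross-check of the quadrature (the two measures
    agree to O(k^2), i.e. within 1% for k <= 0.3).
    """
    k = np.asarray(k, dtype=float)
    return special.j0(k), 0.5 * (1.0 + special.j0(2.0 * k)), 0.5


def arc_length(geom: CrimpGeometry) -> float:
    """Centerline arc length over one period, 4 ell sqrt(1+k^2) E(m).

    ``E`` is the complete elliptic integral of the second kind with
    parameter ``m = k^2 / (1 + k^2)``.
    """
    k = geom.k
    m = k**2 / (1.0 + k**2)
    return float(4.0 * geom.ell * np.sqrt(1.0 + k**2) * special.ellipe(m))


def _rho(k):
    """Arc length over chord length of one period as a function of k = h/ell."""
    k = np.asarray(k, dtype=float)
    m = k**2 / (1.0 + k**2)
    return (2.0 / np.pi) * np.sqrt(1.0 + k**2) * special.ellipe(m)


@dataclass(frozen=True)
class CrimpedFiberState:
    """Per fiber family: crimp geometry, chord strain and chord modulus."""

    geometry: CrimpGeometry
    E_f: float                  # straight-fiber Young's modulus (Pa or MPa)
    eps_chord: float = 0.0      # accumulated along-the-chord strain
    E_chord: float = None       # current chord modulus
    h0: float = None
    ell0: float = None

    def __post_init__(self):
        if self.h0 is None:
            object.__setattr__(self, "h0", self.geometry.h)
        if self.ell0 is None:
            object.__setattr__(self, "ell0", self.geometry.ell)
        if self.E_chord is None:
            object.__setattr__(self, "E_chord", chord_modulus(self.E_f, self.geometry))

    @property
    def recruited(self) -> bool:
        return self.geometry.h == 0.0


def chord_strain_increment(c_dir: np.ndarray, d_fiber: np.ndarray) -> float:
    """Along-the-chord strain increment ``c . d . c`` for a unit fiber axis.

    ``d_fiber`` is the per-increment fiber-phase strain tensor (the solver
    uses a unit pseudo-time step, so strain-rate tensors are increments).
    """
    c = np.asarray(c_dir, dtype=float)
    if abs(np.linalg.norm(c) - 1.0) > 1e-8:
        raise ValueError("fiber direction must be a unit vector")
    d = np.asarray(d_fiber, dtype=float)
    return float(c @ d @ c)


def update_crimp(state: CrimpedFiberState, d_eps: float) -> CrimpedFiberState:
    """Advance the crimp geometry by a chord-strain increment.

    The period stretches affinely with the accumulated chord strain, the
    amplitude follows from arc-length conservation of the inextensible
    centerline, and full recruitment (h = 0, E_c = E_f) is reached when the
    chord catches up with the initial arc length.
    """
    if not np.isfinite(d_eps):
        raise ValueError("chord-strain increment must be finite")
    eps = state.eps_chord + d_eps
    if eps < -1.0:
        raise ValueError("accumulated chord strain below -1 is non-physical")
    ell = state.ell0 * (1.0 + eps)
    k0 = state.h0 / state.ell0
    target = _rho(k0) / (1.0 + eps)   # required arc/chord ratio at new period
    if target <= 1.0:
        geom = CrimpGeometry(0.0, ell, state.geometry.r_c)
        return replace(state, geometry=geom, eps_chord=eps, E_chord=state.E_f)
    hi = max(2.0 * k0, 1.0)
    while _rho(hi) < target:
        hi *= 2.0
    k = optimize.brentq(lambda x: _rho(x) - target, 0.0, hi, xtol=1e-14)
    geom = CrimpGeometry(k * ell, ell, state.geometry.r_c)
    return replace(
        state, geometry=geom, eps_chord=eps,
        E_chord=chord_modulus(state.E_f, geom),
    )


class FiberRecruitment:
    """Vectorized recruitment map eps -> (k, E_c/E_f) for one fiber family.

    Precomputes the inverse of the monotone arc/chord ratio ``rho(k)`` on a
    dense grid so that whole Gauss-point batches are evaluated with a single
    ``np.interp`` call inside the finite-element constitutive update.
    """

    _KGRID = np.linspace(0.0, 2.0, 4001)
    _RHOGRID = _rho(_KGRID)

    def __init__(self, k0: float, r_over_ell0: float):
        if k0 < 0 or r_over_ell0 <= 0:
            raise ValueError("require k0 >= 0 and r_over_ell0 > 0")
        if k0 > self._KGRID[-1]:
            raise ValueError("initial crimp ratio beyond tabulated range")
        self.k0 = float(k0)
        self.r_over_ell0 = float(r_over_ell0)
        self.rho0 = float(_rho(k0))

    def evaluate(self, eps: np.ndarray, measure: str = "arc"):
        """Return ``(k, E_ratio)`` arrays for accumulated chord strains ``eps``."""
        eps = np.asarray(eps, dtype=float)
        target = self.rho0 / (1.0 + eps)
        k = np.interp(target, self._RHOGRID, self._KGRID)
        k = np.where(target <= 1.0, 0.0, k)
        r_over_ell = self.r_over_ell0 / (1.0 + eps)
        e_ratio = chord_modulus_ratio(k, r_over_ell, measure)
        return k, np.where(k == 0.0, 1.0, e_ratio)

    def curve(self, eps_max: float = 0.05, n: int = 200,
              csv_path=None) -> np.ndarray:
        """Recruitment curve: columns (chord stretch 1+eps, E_c/E_f).

        Optionally written as a two-column CSV with header.
        """
        eps = np.linspace(0.0, eps_max, n)
        _, e_ratio = self.evaluate(eps)
        out = np.column_stack([1.0 + eps, e_ratio])
        if csv_path is not None:
            np.savetxt(csv_path, out, delimiter=",", comments="",
                       header="chord_stretch,E_chord_over_E_fiber")
        return out
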