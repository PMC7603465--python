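"""Tension-inflation case studies and their post-processing.

The two experimental protocols simulated here are classical artery tests on
a two-layer cylindrical segment:

* **S-test** (axial tension at constant pressure): the inner pressure is
  first ramped to its target in steps of ``dP``, then the axial stretch is
  ramped from 1 to ``stretch_max`` in steps of ``dlam`` while the pressure
  is held (as a follower load on the deforming inner surface).
* **P-test** (inflation at constant stretch): the axial stretch is first
  ramped to its target, then the pressure from 0 to ``p_max``.

Outputs are per-increment averages over the central region — the axial span
of length L/4 centered at mid-length — which avoids the clamped-end
boundary layers, mirroring how microstructure is imaged at the center of
real samples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fem_solver as fem
from . import tensors as tn
from .material import AdventitiaMaterial, MediaMaterial
from .mesh import build_cylinder_mesh

__all__ = [
    "CaseConfig",
    "generate_fixture",
    "make_simulation",
    "run_tension_inflation",
    "run_s_test",
    "run_p_test",
    "run_disorder_sweep",
    "shear_stiffness_series",
]


@dataclass
class CaseConfig:
    """Full parameter set of one simulated tension-inflation case.

    Lengths in mm (crimp lengths in micrometers), moduli in MPa, pressures
    in mmHg, angles in degrees.  ``R_o`` is the outer radius; the wall of
    thickness ``delta_o`` is split into media (inner, ``delta_M``) and
    adventitia (outer, ``delta_A = delta_o - delta_M``).
    """

    name: str = "custom"
    # geometry
    L_o: float = 7.8
    R_o: float = 1.2
    delta_o: float = 0.19
    delta_M: float = 0.125
    # adventitial microstructure
    f_c: float = 0.15                     # collagen volume fraction
    theta_o: list = field(default_factory=lambda: [60.0, -60.0, 10.0, -10.0])
    phi_o: list = field(default_factory=lambda: [90.0, -90.0, 90.0, -90.0])
    h0_over_ell0: float = 0.2             # initial crimp amplitude / period
    rc_over_ell0: float = 0.04            # fiber radius / period
    ell0_um: float = 50.0                 # initial crimp period (micrometers)
    # phase properties
    E_m: float = 0.01                     # matrix modulus (MPa)
    nu_m: float = 0.4
    E_M: float = 0.12                     # media modulus (MPa)
    nu_M: float = 0.49
    E_f: float = 50.0                     # straight collagen fiber modulus (MPa)
    nu_c: float = 0.35
    # load discretization
    dP_mmHg: float = 5.0
    dlam: float = 0.03
    # spatial discretization (None -> target edge length R_o / 12)
    mesh_size: float | None = None
    n_circ: int | None = None
    n_axial: int | None = None
    n_rad_media: int | None = None
    n_rad_adv: int | None = None
    corotational: bool = False

    def __post_init__(self):
        if len(self.theta_o) != len(self.phi_o):
            raise ValueError("theta_o and phi_o must have the same length")
        if not 0.0 < self.delta_M < self.delta_o < self.R_o:
            raise ValueError("layer thicknesses inconsistent with the radius")
        if not 0.0 <= self.f_c < 1.0:
            raise ValueError("collagen fraction must lie in [0, 1)")
        for v in (self.L_o, self.dP_mmHg, self.dlam, self.E_m, self.E_M,
                  self.E_f, self.h0_over_ell0, self.rc_over_ell0, self.ell0_um):
            if v < 0:
                raise ValueError("negative parameter in configuration")

    @property
    def delta_A(self) -> float:
        return self.delta_o - self.delta_M

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CaseConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


_FIXTURES = {
    "s_test": dict(
        name="s_test", L_o=7.8, R_o=1.2, delta_o=0.19, delta_M=0.125,
        f_c=0.15, theta_o=[60.0, -60.0, 10.0, -10.0],
        phi_o=[90.0, -90.0, 90.0, -90.0], h0_over_ell0=0.2,
    ),
    "p_test": dict(
        name="p_test", L_o=8.0, R_o=1.1, delta_o=0.155, delta_M=0.1,
        f_c=0.20, theta_o=[70.0, -70.0, 35.0, -35.0],
        phi_o=[90.0, -90.0, 90.0, -90.0], h0_over_ell0=0.25,
    ),
}


def generate_fixture(name: str) -> CaseConfig:
    """Named, fully validated configurations.

    ``s_test`` and ``p_test`` are the two tension-inflation parameter
    columns; ``disorder`` is the stretching-test (s_test) column used by the
    collagen-disorder sweeps; ``tiny`` is a coarse, fast variant of s_test
    for smoke tests (coarse mesh and doubled load steps, same physics).
    """
    if name in _FIXTURES:
        return CaseConfig(**_FIXTURES[name])
    if name == "disorder":
        cfg = CaseConfig(**_FIXTURES["s_test"])
        cfg.name = "disorder"
        return cfg
    if name == "tiny":
        cfg = CaseConfig(**_FIXTURES["s_test"])
        cfg.name = "tiny"
        cfg.n_circ, cfg.n_axial = 8, 4
        cfg.n_rad_media, cfg.n_rad_adv = 2, 1
        cfg.dP_mmHg, cfg.dlam = 10.0, 0.06
        return cfg
    raise ValueError(f"unknown fixture {name!r}")


def make_simulation(config: CaseConfig) -> fem.Simulation:
    """Mesh + materials + simulation object for a configuration."""
    mesh = build_cylinder_mesh(
        config.R_o, config.delta_o, config.delta_M, config.L_o,
        mesh_size=config.mesh_size, n_circ=config.n_circ,
        n_axial=config.n_axial, n_rad_media=config.n_rad_media,
        n_rad_adv=config.n_rad_adv,
    )
    media = MediaMaterial(config.E_M, config.nu_M,
                          corotational=config.corotational)
    adventitia = AdventitiaMaterial(
        E_m=config.E_m, nu_m=config.nu_m, f_c=config.f_c, E_f=config.E_f,
        nu_c=config.nu_c, theta0=np.radians(config.theta_o),
        phi0=np.radians(config.phi_o), h0_over_ell0=config.h0_over_ell0,
        rc_over_ell0=config.rc_over_ell0, corotational=config.corotational,
    )
    return fem.Simulation(mesh, media, adventitia)


# ----------------------------------------------------------------------
# Central-region post-processing
# ----------------------------------------------------------------------

def _central_masks(sim: fem.Simulation):
    """Element and adventitia-Gauss-point masks of the central L/4 span."""
    mesh = sim.mesh
    cent = mesh.element_centroids(sim.coords)
    zmax = sim.coords[:, 2].max()
    dz = np.abs(cent[:, 2] - 0.5 * zmax)
    # on very coarse meshes the L/4 window can fall between centroid layers;
    # widen it just enough to always include the elements nearest mid-length
    half_span = max(zmax / 8.0, dz.min()) + 1e-9
    in_span = dz <= half_span
    # select adventitia elements with their own window so boundary-layer
    # shifts of the outer layer cannot empty the fiber averages
    dz_adv = dz[sim.adv_els]
    adv_span = max(zmax / 8.0, dz_adv.min() if len(dz_adv) else 0.0) + 1e-9
    gp_in = np.repeat(dz_adv <= adv_span, 8)
    return in_span, gp_in


def central_summary(sim: fem.Simulation, stretch: float) -> dict:
    """One row of the central-region summary at the current state."""
    mesh = sim.mesh
    adv = sim.adventitia
    el_mask, gp_mask = _central_masks(sim)
    cent = mesh.element_centroids(sim.coords)
    cent0 = mesh.element_centroids(mesh.nodes)
    r = np.hypot(cent[el_mask, 0], cent[el_mask, 1])
    r0 = np.hypot(cent0[el_mask, 0], cent0[el_mask, 1])
    rel_diameter = r.mean() / r0.mean()

    # volume-weighted axial Cauchy stress over all central Gauss points
    _, detJ, _ = fem.shape_gradients_at_gauss(sim.coords, mesh.elements)
    s_zz = tn.from_mandel(sim.stresses6())[..., 2, 2]
    w = detJ[el_mask].ravel()
    axial_stress = np.average(s_zz[el_mask].ravel(), weights=w)

    row = {
        "pressure_mmHg": sim.pressure / fem.MMHG_TO_MPA,
        "stretch": stretch,
        "rel_diameter": rel_diameter,
        "axial_stress_kPa": 1e3 * axial_stress,
        "mean_disp_norm_mm": float(np.linalg.norm(
            sim.coords - mesh.nodes, axis=1)[_central_node_mask(sim)].mean()),
    }

    if adv.nf:
        st = sim.state_adv
        theta = np.degrees(adv.theta_angles(st))      # [0, 90], 0 = axial
        row["theta1_deg"] = float(theta[gp_mask, 0].mean())
        # fiber stress: along-fiber stress of the main +-theta1 pair
        fs = adv.fiber_axial_stress(st)[:, :2].mean(axis=1)
        row["fiber_stress_kPa"] = 1e3 * float(fs[gp_mask].mean())
        row["crimp_ratio1"] = float(st.crimp_k[gp_mask, 0].mean())
        row["chord_modulus_ratio1"] = float(st.E_ratio[gp_mask, 0].mean())
        # axial-circumferential shear modulus of the homogenized tangent,
        # expressed in the local wall frame: Mandel (K,T) shear entry / 2
        R = np.swapaxes(st.lrs, -1, -2)               # columns K, T, N
        Q = tn.mandel_rotation(R)
        C_loc = np.swapaxes(Q, -1, -2) @ st.tangent6 @ Q
        row["shear_stiffness_kPa"] = 1e3 * float(
            0.5 * C_loc[gp_mask, 5, 5].mean())
    return row


def _central_node_mask(sim: fem.Simulation) -> np.ndarray:
    z = sim.coords[:, 2]
    zmax = z.max()
    return np.abs(z - 0.5 * zmax) <= zmax / 8.0 + 1e-9


# ----------------------------------------------------------------------
# Protocol runners
# ----------------------------------------------------------------------

def run_tension_inflation(
    config: CaseConfig,
    pressure_mmHg: float,
    stretch_max: float,
    p_first: bool = True,
    sim: fem.Simulation | None = None,
) -> pd.DataFrame:
    """Generic two-stage protocol driver; returns the per-increment summary.

    ``p_first=True`` ramps pressure then stretch (S-test order); ``False``
    ramps stretch then pressure (P-test order).  The axial tangent
    stiffness column is the finite-difference slope of the axial-stress
    series with respect to stretch (meaningful during the stretch stage).
    """
    sim = sim or make_simulation(config)
    rows = [central_summary(sim, 1.0)]

    def pressure_ramp(target):
        n = max(1, round(target / config.dP_mmHg))
        for p in np.linspace(target / n, target, n):
            sim.step(p * fem.MMHG_TO_MPA, 0.0)
            rows.append(central_summary(sim, 1.0 + sim.axial_displacement / config.L_o))

    def stretch_ramp(target, held_pressure):
        lam = 1.0 + sim.axial_displacement / config.L_o
        while lam < target - 1e-9:
            dlam = min(config.dlam, target - lam)
            sim.step(held_pressure * fem.MMHG_TO_MPA, dlam * config.L_o)
            lam += dlam
            rows.append(central_summary(sim, lam))

    if p_first:
        pressure_ramp(pressure_mmHg)
        stretch_ramp(stretch_max, pressure_mmHg)
    else:
        stretch_ramp(stretch_max, 0.0)
        pressure_ramp(pressure_mmHg)

    df = pd.DataFrame(rows)
    df.index.name = "increment"
    with np.errstate(divide="ignore", invalid="ignore"):
        dlam = np.gradient(df["stretch"].to_numpy())
        dsig = np.gradient(df["axial_stress_kPa"].to_numpy())
        df["axial_stiffness_kPa"] = np.where(dlam > 1e-12, dsig / dlam, np.nan)
    return df


def run_s_test(config: CaseConfig, pressure_mmHg: float = 20.0,
               stretch_max: float = 1.8) -> pd.DataFrame:
    """Axial tension under constant pressure (pressure ramped first)."""
    return run_tension_inflation(config, pressure_mmHg, stretch_max, p_first=True)


def run_p_test(config: CaseConfig, stretch: float = 1.5,
               p_max_mmHg: float = 140.0) -> pd.DataFrame:
    """Inflation under constant axial stretch (stretch ramped first)."""
    if stretch < 1.0:
        raise ValueError("stretch must be >= 1")
    return run_tension_inflation(config, p_max_mmHg, stretch, p_first=False)


def run_disorder_sweep(config: CaseConfig, param: str, values) -> dict:
    """Stretching test (P = 20 mmHg, stretch to 1.6) over a parameter sweep.

    ``param`` is ``"f_c"`` (collagen volume fraction) or ``"h0"`` (initial
    crimp amplitude, in units of the initial period).  Returns
    ``{"series": {value: DataFrame}, "table": DataFrame}`` where the table
    collects the central-region fiber stress, axial tissue stress and axial
    tangent stiffness at the final stretch for each value.
    """
    if param not in ("f_c", "h0"):
        raise ValueError("param must be 'f_c' or 'h0'")
    series, rows = {}, []
    for v in values:
        if v <= 0:
            raise ValueError("sweep values must be positive")
        cfg = dataclasses.replace(config)
        if param == "f_c":
            cfg.f_c = float(v)
        else:
            cfg.h0_over_ell0 = float(v)
        df = run_s_test(cfg, pressure_mmHg=20.0, stretch_max=1.6)
        series[v] = df
        last = df.iloc[-1]
        rows.append({
            param: v,
            "fiber_stress_kPa": last["fiber_stress_kPa"],
            "axial_stress_kPa": last["axial_stress_kPa"],
            "axial_stiffness_kPa": last["axial_stiffness_kPa"],
            "crimped": bool(last["crimp_ratio1"] > 1e-6),
        })
    table = pd.DataFrame(rows).set_index(param)
    return {"series": series, "table": table}


def shear_stiffness_series(config: CaseConfig, mode: str) -> pd.DataFrame:
    """Axial-circumferential shear stiffness during one of two protocols.

    ``mode="stretch"``: stretching test under constant 120 mmHg;
    ``mode="inflate"``: inflation test at constant stretch 1.3.  The shear
    stiffness is the (K, T) shear component of the homogenized adventitial
    tangent in the local wall frame, averaged over the central region.
    """
    if mode == "stretch":
        return run_s_test(config, pressure_mmHg=120.0, stretch_max=1.8)
    if mode == "inflate":
        return run_p_test(config, stretch=1.3, p_max_mmHg=140.0)
    raise ValueError("mode must be 'stretch' or 'inflate'")
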