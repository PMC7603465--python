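"""Result export: HDF5 state dumps, CSV summaries and legacy-ASCII VTK files.

The VTK writer emits the legacy unstructured-grid format (readable by
ParaView and VisIt) with per-cell data: layer tag, main-family fiber angle,
axial Cauchy stress and displacement norm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fem_solver as fem
from . import tensors as tn

__all__ = ["save_summary_csv", "save_results_h5", "write_vtk"]


def save_summary_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True)


def save_results_h5(path, config, summary: pd.DataFrame,
                    sim: fem.Simulation | None = None) -> None:
    """Write the configuration, summary table and (optionally) final state."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("config")
        for k, v in config.to_dict().items():
            g.attrs[k] = "" if v is None else v
        s = f.create_group("summary")
        for col in summary.columns:
            s.create_dataset(col, data=summary[col].to_numpy())
        if sim is not None:
            st = f.create_group("final_state")
            st.create_dataset("coords", data=sim.coords)
            st.create_dataset("displacement", data=sim.coords - sim.mesh.nodes)
            st.create_dataset("elements", data=sim.mesh.elements)
            st.create_dataset("layer", data=sim.mesh.layer)
            st.attrs["pressure_MPa"] = sim.pressure
            st.attrs["axial_displacement_mm"] = sim.axial_displacement


def _cell_fields(sim: fem.Simulation) -> dict:
    mesh = sim.mesh
    ne = len(mesh.elements)
    s_zz = tn.from_mandel(sim.stresses6())[..., 2, 2].mean(axis=1)
    disp = np.linalg.norm(sim.coords - mesh.nodes, axis=1)
    u_cell = disp[mesh.elements].mean(axis=1)
    theta1 = np.full(ne, np.nan)
    if sim.adventitia.nf and len(sim.adv_els):
        th = np.degrees(sim.adventitia.theta_angles(sim.state_adv))[:, 0]
        theta1[sim.adv_els] = th.reshape(len(sim.adv_els), 8).mean(axis=1)
    return {
        "layer": mesh.layer.astype(float),
        "theta1_deg": theta1,
        "axial_stress_MPa": s_zz,
        "disp_norm_mm": u_cell,
    }


def write_vtk(path, sim: fem.Simulation) -> None:
    """Legacy-ASCII VTK unstructured grid of the current deformed state."""
    mesh = sim.mesh
    pts = sim.coords
    cells = mesh.elements
    fields = _cell_fields(sim)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("arterysim deformed state\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        np.savetxt(f, pts, fmt="%.9g")
        f.write(f"CELLS {len(cells)} {9 * len(cells)}\n")
        np.savetxt(f, np.hstack([np.full((len(cells), 1), 8), cells]), fmt="%d")
        f.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(f, np.full(len(cells), 12), fmt="%d")   # VTK_HEXAHEDRON
        f.write(f"CELL_DATA {len(cells)}\n")
        for name, data in fields.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, np.nan_to_num(data, nan=-1.0), fmt="%.9g")
        f.write(f"POINT_DATA {len(pts)}\n")
        f.write("VECTORS displacement double\n")
        np.savetxt(f, sim.coords - mesh.nodes, fmt="%.9g")
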