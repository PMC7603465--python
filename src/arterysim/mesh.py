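"""Structured hex8 mesh of the two-layer hollow arterial cylinder.

Geometry convention: ``R_o`` is the outer radius, the wall occupies
``[R_o - delta_o, R_o]`` with the media as the inner layer (thickness
``delta_M``) and the adventitia as the outer one (``delta_A``); the layer
interface sits at ``R_o - delta_o + delta_M``.  The cylinder axis is the
global z axis; the left end (z = 0) is the fully clamped section and the
right end (z = L) the loaded one.  All lengths in millimetres.

The mesh is a structured grid: ``n_rad`` element layers through the wall
(split between media and adventitia at the interface), ``n_circ`` around
the circumference (wrapping), ``n_axial`` along the axis.  Inner-surface
facets are stored with a node ordering whose parametric cross product
points radially OUTWARD, so a positive pressure applied along that vector
inflates the vessel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Mesh", "build_cylinder_mesh"]


@dataclass
class Mesh:
    nodes: np.ndarray          # (N, 3) reference coordinates, mm
    elements: np.ndarray       # (E, 8) hex8 connectivity
    layer: np.ndarray          # (E,) 0 = media, 1 = adventitia
    inner_facets: np.ndarray   # (Fi, 4) quad facets on the inner surface
    outer_facets: np.ndarray   # (Fe, 4)
    sigma_minus: np.ndarray    # node ids, clamped end (z = 0)
    sigma_plus: np.ndarray     # node ids, loaded end (z = L)
    r_inner: float
    r_interface: float
    r_outer: float
    length: float
    divisions: tuple = field(default=None)   # (n_rad_media, n_rad_adv, n_circ, n_axial)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def element_centroids(self, coords: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if coords is None else coords
        return x[self.elements].mean(axis=1)


def build_cylinder_mesh(
    r_outer: float,
    thickness: float,
    thickness_media: float,
    length: float,
    mesh_size: float | None = None,
    n_circ: int | None = None,
    n_axial: int | None = None,
    n_rad_media: int | None = None,
    n_rad_adv: int | None = None,
) -> Mesh:
    """Build the structured two-layer cylinder mesh.

    ``mesh_size`` is the target edge length (default ``r_outer / 12``); the
    explicit division counts override it, which is how scaled-down runs
    coarsen the model.  At the default size, at least 3 element layers are
    placed through the media and 2 through the adventitia.
    """
    if min(r_outer, thickness, thickness_media, length) <= 0:
        raise ValueError("geometry parameters must be positive")
    if thickness_media >= thickness:
        raise ValueError("media thickness must be smaller than the wall thickness")
    if thickness >= r_outer:
        raise ValueError("wall thicker than the outer radius")
    size = r_outer / 12.0 if mesh_size is None else float(mesh_size)
    t_adv = thickness - thickness_media
    n_rm = n_rad_media or max(3, round(thickness_media / size))
    n_ra = n_rad_adv or max(2, round(t_adv / size))
    r_mid = r_outer - 0.5 * thickness
    nc = n_circ or max(8, round(2.0 * np.pi * r_mid / size))
    nz = n_axial or max(2, round(length / size))

    r_in = r_outer - thickness
    r_int = r_in + thickness_media
    radii = np.concatenate([
        np.linspace(r_in, r_int, n_rm + 1),
        np.linspace(r_int, r_outer, n_ra + 1)[1:],
    ])
    nr = n_rm + n_ra
    angles = np.linspace(0.0, 2.0 * np.pi, nc, endpoint=False)
    zs = np.linspace(0.0, length, nz + 1)

    # node id = (iz * (nr+1) + ir) * nc + ic
    R, A = np.meshgrid(radii, angles, indexing="ij")
    ring = np.stack([R * np.cos(A), R * np.sin(A)], axis=-1)  # (nr+1, nc, 2)
    nodes = np.empty(((nz + 1) * (nr + 1) * nc, 3))
    for iz, z in enumerate(zs):
        base = iz * (nr + 1) * nc
        nodes[base:base + (nr + 1) * nc, :2] = ring.reshape(-1, 2)
        nodes[base:base + (nr + 1) * nc, 2] = z

    def nid(iz, ir, ic):
        return (iz * (nr + 1) + ir) * nc + (ic % nc)

    elems, layer = [], []
    for iz in range(nz):
        for ir in range(nr):
            for ic in range(nc):
                elems.append([
                    nid(iz, ir, ic), nid(iz, ir + 1, ic),
                    nid(iz, ir + 1, ic + 1), nid(iz, ir, ic + 1),
                    nid(iz + 1, ir, ic), nid(iz + 1, ir + 1, ic),
                    nid(iz + 1, ir + 1, ic + 1), nid(iz + 1, ir, ic + 1),
                ])
                layer.append(0 if ir < n_rm else 1)

    inner, outer = [], []
    for iz in range(nz):
        for ic in range(nc):
            # ordering: (circumferential tangent) x (axial tangent) = +e_r
            inner.append([nid(iz, 0, ic), nid(iz, 0, ic + 1),
                          nid(iz + 1, 0, ic + 1), nid(iz + 1, 0, ic)])
            outer.append([nid(iz, nr, ic), nid(iz, nr, ic + 1),
                          nid(iz + 1, nr, ic + 1), nid(iz + 1, nr, ic)])

    sigma_minus = np.arange((nr + 1) * nc)
    sigma_plus = nz * (nr + 1) * nc + np.arange((nr + 1) * nc)

    mesh = Mesh(
        nodes=nodes,
        elements=np.asarray(elems, dtype=np.int64),
        layer=np.asarray(layer, dtype=np.int8),
        inner_facets=np.asarray(inner, dtype=np.int64),
        outer_facets=np.asarray(outer, dtype=np.int64),
        sigma_minus=sigma_minus,
        sigma_plus=sigma_plus,
        r_inner=r_in,
        r_interface=r_int,
        r_outer=r_outer,
        length=length,
        divisions=(n_rm, n_ra, nc, nz),
    )
    _check_jacobians(mesh)
    return mesh


def _check_jacobians(mesh: Mesh) -> None:
    from .fem_solver import shape_gradients_at_gauss

    dNdx, detJ, _ = shape_gradients_at_gauss(mesh.nodes, mesh.elements)
    if np.any(detJ <= 0.0):
        raise ValueError("mesh has non-positive Jacobians (degenerate geometry)")
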