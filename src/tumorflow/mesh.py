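"""Triangulated disc meshes of the three concentric tumor regions.

The generator is a deterministic structured polar ("spiderweb") scheme:
nodes are placed on concentric rings whose radial spacing and per-ring
node count both track the requested maximum edge length, the two internal
interface circles and the outer boundary are meshed exactly as rings, and
consecutive rings are stitched by an angular two-pointer sweep.  Elements
are linear (3-node) or quadratic (6-node) triangles; quadratic mid-edge
nodes that lie on one of the three circles are snapped to the exact
circle so curved interfaces are represented to quadratic geometric order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .parameters import TumorGeometry, REGION_NAMES

__all__ = [
    "Mesh",
    "build_disc_mesh",
    "refinement_ladder",
    "rotated",
    "LADDER_H",
    "DEFAULT_H",
]

#: maximum-edge-length refinement ladder [cm] (test cases 1-5)
LADDER_H = (0.2, 0.1, 0.05, 0.03, 0.01)
#: default working mesh (case 4)
DEFAULT_H = 0.03


@dataclass
class Mesh:
    """Unstructured triangle mesh of the disc.

    ``elements`` references 3 nodes (corners, CCW) for linear order or
    6 nodes (corners then mid-edge nodes opposite the usual convention:
    m01, m12, m20) for quadratic order.  ``region_tag`` holds integer
    codes 0/1/2 for necrotic/viable/healthy.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region_tag: np.ndarray
    boundary_edges: np.ndarray
    h_max: float
    order: int
    geometry: TumorGeometry
    seed: Optional[int] = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def region_names(self) -> np.ndarray:
        return np.array(REGION_NAMES)[self.region_tag]

    def corner_coords(self) -> np.ndarray:
        """(E, 3, 2) corner coordinates."""
        return self.nodes[self.elements[:, :3]]

    def signed_areas(self) -> np.ndarray:
        c = self.corner_coords()
        return 0.5 * ((c[:, 1, 0] - c[:, 0, 0]) * (c[:, 2, 1] - c[:, 0, 1])
                      - (c[:, 2, 0] - c[:, 0, 0]) * (c[:, 1, 1] - c[:, 0, 1]))

    def centroids(self) -> np.ndarray:
        return self.corner_coords().mean(axis=1)

    def min_angle_deg(self) -> float:
        """Smallest interior angle over all elements (corner triangles)."""
        c = self.corner_coords()
        angles = []
        for i in range(3):
            a = c[:, (i + 1) % 3] - c[:, i]
            b = c[:, (i + 2) % 3] - c[:, i]
            cosang = (a * b).sum(1) / (np.linalg.norm(a, axis=1)
                                       * np.linalg.norm(b, axis=1))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))


def _ring_radii(geom: TumorGeometry, h: float):
    """Ring radii resolving the two interfaces exactly; per-ring spacing."""
    radii = [0.0]
    spacing = [h]
    for ra, rb in ((0.0, geom.Rnt), (geom.Rnt, geom.Rvt), (geom.Rvt, geom.Rht)):
        m = max(1, math.ceil((rb - ra) / h))
        seg = np.linspace(ra, rb, m + 1)[1:]
        radii.extend(seg.tolist())
        spacing.extend([(rb - ra) / m] * m)
    return np.array(radii), np.array(spacing)


def _stitch(inner: np.ndarray, outer: np.ndarray,
            ain: np.ndarray, aout: np.ndarray) -> list:
    """Triangulate the annulus between two node rings by angle merge."""
    n_in, n_out = len(inner), len(outer)
    tris = []
    i = j = 0
    twopi = 2.0 * math.pi
    while i < n_in or j < n_out:
        nxt_in = ain[i + 1] if i + 1 < n_in else (twopi + ain[0] if i < n_in else np.inf)
        nxt_out = aout[j + 1] if j + 1 < n_out else (twopi + aout[0] if j < n_out else np.inf)
        if j < n_out and (i >= n_in or nxt_out <= nxt_in):
            tris.append((inner[i % n_in], outer[j % n_out], outer[(j + 1) % n_out]))
            j += 1
        else:
            tris.append((inner[i % n_in], outer[j % n_out], inner[(i + 1) % n_in]))
            i += 1
    return tris


def build_disc_mesh(
    geom: TumorGeometry,
    h_max: float,
    order: int = 1,
    seed: Optional[int] = None,
) -> Mesh:
    """Conforming triangulation of the disc of radius R_ht.

    The internal circles at R_nt and R_vt are resolved as node rings
    (vertex spacing <= ``h_max``), elements are tagged by centroid radius
    with half-open bins, and the construction is fully deterministic for
    a given ``(geom, h_max, order)``; ``seed`` is recorded for provenance
    only.

    Raises
    ------
    ValueError
        If ``h_max <= 0`` or ``h_max >= R_nt`` (interface unresolvable).
    """
    if h_max <= 0:
        raise ValueError("h_max must be positive")
    if h_max >= geom.Rnt:
        raise ValueError(
            f"h_max={h_max} cannot resolve the necrotic interface at "
            f"Rnt={geom.Rnt}")
    if order not in (1, 2):
        raise ValueError("order must be 1 (linear) or 2 (quadratic)")

    radii, spacing = _ring_radii(geom, h_max)
    nodes = [(0.0, 0.0)]
    rings = [np.array([0])]
    ring_angles = [np.array([0.0])]
    for r, dr in zip(radii[1:], spacing[1:]):
        n = max(6, int(round(2.0 * math.pi * r / dr)))
        theta = 2.0 * math.pi * np.arange(n) / n
        start = len(nodes)
        nodes.extend(zip(r * np.cos(theta), r * np.sin(theta)))
        rings.append(start + np.arange(n))
        ring_angles.append(theta)
    nodes = np.array(nodes, dtype=float)

    tris = []
    # center fan
    r1 = rings[1]
    n1 = len(r1)
    for i in range(n1):
        tris.append((0, r1[i], r1[(i + 1) % n1]))
    for k in range(1, len(rings) - 1):
        tris.extend(_stitch(rings[k], rings[k + 1],
                            ring_angles[k], ring_angles[k + 1]))
    elements = np.array(tris, dtype=np.int64)

    # enforce CCW orientation
    c = nodes[elements]
    sa = 0.5 * ((c[:, 1, 0] - c[:, 0, 0]) * (c[:, 2, 1] - c[:, 0, 1])
                - (c[:, 2, 0] - c[:, 0, 0]) * (c[:, 1, 1] - c[:, 0, 1]))
    flip = sa < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    cent = nodes[elements].mean(axis=1)
    rc = np.hypot(cent[:, 0], cent[:, 1])
    region_tag = np.digitize(rc, [geom.Rnt, geom.Rvt]).astype(np.int8)

    outer = rings[-1]
    nb = len(outer)
    boundary_edges = np.stack(
        [outer, np.roll(outer, -1)], axis=1).astype(np.int64)

    if order == 2:
        nodes, elements = _quadratize(nodes, elements, geom)

    return Mesh(nodes=nodes, elements=elements, region_tag=region_tag,
                boundary_edges=boundary_edges, h_max=h_max, order=order,
                geometry=geom, seed=seed)


def _quadratize(nodes: np.ndarray, elements: np.ndarray,
                geom: TumorGeometry) -> tuple:
    """Add mid-edge nodes; snap mid-edge nodes of circle edges to the circle."""
    circles = np.array([geom.Rnt, geom.Rvt, geom.Rht])
    rnode = np.hypot(nodes[:, 0], nodes[:, 1])
    # circle membership of each corner node (-1 if none)
    on_circle = np.full(len(nodes), -1, dtype=np.int8)
    for ci, R in enumerate(circles):
        on_circle[np.abs(rnode - R) < 1e-9 * max(1.0, R)] = ci

    edge_mid: dict = {}
    new_nodes = [nodes]
    extra = []
    counter = len(nodes)
    mids_per_elem = np.empty((len(elements), 3), dtype=np.int64)
    for e, (a, b, c) in enumerate(elements):
        for k, (p, q) in enumerate(((a, b), (b, c), (c, a))):
            key = (p, q) if p < q else (q, p)
            idx = edge_mid.get(key)
            if idx is None:
                xm = 0.5 * (nodes[p] + nodes[q])
                cp, cq = on_circle[p], on_circle[q]
                if cp >= 0 and cp == cq:
                    R = circles[cp]
                    nrm = math.hypot(xm[0], xm[1])
                    if nrm > 0:
                        xm = xm * (R / nrm)
                idx = counter
                counter += 1
                extra.append(xm)
                edge_mid[key] = idx
            mids_per_elem[e, k] = idx
    all_nodes = np.vstack([nodes, np.array(extra)])
    quad_elements = np.hstack([elements, mids_per_elem])
    return all_nodes, quad_elements


def refinement_ladder(geom: TumorGeometry, order: int = 2,
                      h_values=LADDER_H) -> list:
    """Meshes for the standard h_max ladder (coarsest first)."""
    return [build_disc_mesh(geom, h, order=order) for h in h_values]


def rotated(mesh: Mesh, angle_deg: float) -> Mesh:
    """Copy of the mesh with all node coordinates rotated about the origin."""
    a = math.radians(angle_deg)
    R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    return Mesh(nodes=mesh.nodes @ R.T, elements=mesh.elements.copy(),
                region_tag=mesh.region_tag.copy(),
                boundary_edges=mesh.boundary_edges.copy(),
                h_max=mesh.h_max, order=mesh.order,
                geometry=mesh.geometry, seed=mesh.seed)
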