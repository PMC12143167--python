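"""Shared Galerkin element machinery for triangular P1/P2 meshes.

Vectorized over elements: for each quadrature point the Jacobian,
physical shape-function gradients and mapped coordinates are precomputed
once per mesh; stiffness / mass / convection operators and load vectors
are then assembled as COO triplets in a handful of einsum calls.
Quadratic elements are isoparametric, so the curved (circle-snapped)
edges enter through the per-point Jacobian.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .mesh import Mesh

__all__ = ["ElementBatch", "sample_on_points"]


def _quadrature(order: int):
    """Quadrature nodes/weights on the reference triangle (area 1/2)."""
    if order == 1:
        pts = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
        w = np.full(3, 1 / 6)
    else:
        # 7-point degree-5 rule
        a = 0.059715871789770
        b = 0.470142064105115
        c = 0.797426985353087
        d = 0.101286507323456
        pts = np.array([
            [1 / 3, 1 / 3],
            [a, b], [b, a], [b, b],
            [c, d], [d, c], [d, d],
        ])
        w = 0.5 * np.array([
            0.225,
            0.132394152788506, 0.132394152788506, 0.132394152788506,
            0.125939180544827, 0.125939180544827, 0.125939180544827,
        ])
    return pts, w


def _shape(order: int, pts: np.ndarray):
    """Shape functions and reference gradients at the given points."""
    xi, eta = pts[:, 0], pts[:, 1]
    lam = np.stack([1.0 - xi - eta, xi, eta], axis=1)  # (nq, 3)
    dlam = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # (3, 2)
    nq = pts.shape[0]
    if order == 1:
        N = lam
        dN = np.broadcast_to(dlam, (nq, 3, 2)).copy()
        return N, dN
    N = np.empty((nq, 6))
    dN = np.empty((nq, 6, 2))
    for i in range(3):
        N[:, i] = lam[:, i] * (2.0 * lam[:, i] - 1.0)
        dN[:, i, :] = (4.0 * lam[:, i] - 1.0)[:, None] * dlam[i]
    pairs = [(0, 1), (1, 2), (2, 0)]  # mid-edge nodes m01, m12, m20
    for k, (i, j) in enumerate(pairs):
        N[:, 3 + k] = 4.0 * lam[:, i] * lam[:, j]
        dN[:, 3 + k, :] = 4.0 * (lam[:, i][:, None] * dlam[j]
                                 + lam[:, j][:, None] * dlam[i])
    return N, dN


class ElementBatch:
    """Per-quadrature-point element data and assembly helpers for a mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        pts, w = _quadrature(mesh.order)
        self.N, dN = _shape(mesh.order, pts)        # (nq, nn), (nq, nn, 2)
        self.wq = w
        coords = mesh.nodes[mesh.elements]          # (E, nn, 2)
        nq = pts.shape[0]
        E, nn = mesh.elements.shape
        self.nq, self.nn, self.E = nq, nn, E
        self.detJ = np.empty((nq, E))
        self.grads = np.empty((nq, E, nn, 2))
        self.xq = np.empty((nq, E, 2))
        for q in range(nq):
            # J[e, k, j] = d x_k / d xi_j
            J = np.einsum("enk,nj->ekj", coords, dN[q])
            det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            inv = np.empty_like(J)
            inv[:, 0, 0] = J[:, 1, 1] / det
            inv[:, 0, 1] = -J[:, 0, 1] / det
            inv[:, 1, 0] = -J[:, 1, 0] / det
            inv[:, 1, 1] = J[:, 0, 0] / det
            self.detJ[q] = det
            # grad_x N_n = sum_j dN[n, j] * invJ[j, k]
            self.grads[q] = np.einsum("nj,ejk->enk", dN[q], inv)
            self.xq[q] = np.einsum("qn,enk->ek", self.N[q:q + 1], coords)

    # -- coefficient helpers ------------------------------------------------

    def per_element(self, by_region: np.ndarray) -> np.ndarray:
        """Map region-indexed values (len 3) to per-element values."""
        return np.asarray(by_region, dtype=float)[self.mesh.region_tag]

    def _coef_qe(self, coef) -> np.ndarray:
        """Broadcast a coefficient to shape (nq, E)."""
        if coef is None:
            return np.ones((self.nq, self.E))
        coef = np.asarray(coef, dtype=float)
        if coef.ndim == 0:
            return np.full((self.nq, self.E), float(coef))
        if coef.shape == (self.E,):
            return np.broadcast_to(coef, (self.nq, self.E))
        if coef.shape == (self.nq, self.E):
            return coef
        raise ValueError(f"coefficient shape {coef.shape} not understood")

    def interpolate(self, nodal: np.ndarray) -> np.ndarray:
        """Nodal field values at the quadrature points, shape (nq, E)."""
        vals = nodal[self.mesh.elements]            # (E, nn)
        return np.einsum("qn,en->qe", self.N, vals)

    def grad_interpolate(self, nodal: np.ndarray) -> np.ndarray:
        """Gradient of a nodal field at quadrature points, shape (nq, E, 2)."""
        vals = nodal[self.mesh.elements]
        return np.einsum("qenk,en->qek", self.grads, vals)

    # -- assembly -----------------------------------------------------------

    def _scatter(self, Ke: np.ndarray) -> sparse.csr_matrix:
        el = self.mesh.elements
        rows = np.repeat(el, self.nn, axis=1).ravel()
        cols = np.tile(el, (1, self.nn)).ravel()
        n = self.mesh.n_nodes
        return sparse.coo_matrix(
            (Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    def stiffness(self, coef=None) -> sparse.csr_matrix:
        """Assemble ∫ c ∇u·∇v with a scalar coefficient c(x)."""
        c = self._coef_qe(coef)
        Ke = np.einsum("q,qe,qe,qemk,qenk->emn",
                       self.wq, self.detJ, c, self.grads, self.grads)
        return self._scatter(Ke)

    def mass(self, coef=None) -> sparse.csr_matrix:
        """Assemble ∫ c u v."""
        c = self._coef_qe(coef)
        Ke = np.einsum("q,qe,qe,qm,qn->emn",
                       self.wq, self.detJ, c, self.N, self.N)
        return self._scatter(Ke)

    def convection(self, v_nodal: np.ndarray, coef=None) -> sparse.csr_matrix:
        """Assemble ∫ c v·∇u w from a nodal velocity field (n_nodes, 2)."""
        c = self._coef_qe(coef)
        vq = np.stack([self.interpolate(v_nodal[:, 0]),
                       self.interpolate(v_nodal[:, 1])], axis=-1)  # (nq,E,2)
        adv = np.einsum("qek,qenk->qen", vq, self.grads)
        Ke = np.einsum("q,qe,qe,qm,qen->emn",
                       self.wq, self.detJ, c, self.N, adv)
        return self._scatter(Ke)

    def load(self, coef) -> np.ndarray:
        """Assemble the load vector ∫ c v."""
        c = self._coef_qe(coef)
        be = np.einsum("q,qe,qe,qn->en", self.wq, self.detJ, c, self.N)
        b = np.zeros(self.mesh.n_nodes)
        np.add.at(b, self.mesh.elements.ravel(), be.ravel())
        return b

    def integrate(self, coef) -> float:
        """∫ c dΩ for a (nq, E) / per-element / scalar coefficient."""
        c = self._coef_qe(coef)
        return float(np.einsum("q,qe,qe->", self.wq, self.detJ, c))


def sample_on_points(mesh: Mesh, nodal: np.ndarray,
                     points: np.ndarray) -> np.ndarray:
    """Element-local interpolation of a nodal field at arbitrary points.

    Uses a corner-vertex triangulation for point location; quadratic
    fields are evaluated with the P2 shape functions at the barycentric
    coordinates of the straight corner triangle (curvature only affects
    edges on the three circles, an O(h²)-consistent approximation for
    sampling).  Points outside the mesh return NaN.
    """
    from matplotlib.tri import Triangulation

    tri = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1],
                        mesh.elements[:, :3])
    finder = tri.get_trifinder()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    elem = finder(points[:, 0], points[:, 1])
    out = np.full(points.shape[0], np.nan)
    inside = elem >= 0
    if not inside.any():
        return out
    e = elem[inside]
    corners = mesh.nodes[mesh.elements[e, :3]]      # (m, 3, 2)
    v0 = corners[:, 0]
    T = np.stack([corners[:, 1] - v0, corners[:, 2] - v0], axis=-1)
    rhs = points[inside] - v0
    det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
    xi = (T[:, 1, 1] * rhs[:, 0] - T[:, 0, 1] * rhs[:, 1]) / det
    eta = (-T[:, 1, 0] * rhs[:, 0] + T[:, 0, 0] * rhs[:, 1]) / det
    N, _ = _shape(mesh.order, np.stack([xi, eta], axis=1))
    vals = nodal[mesh.elements[e]]
    out[inside] = (N * vals).sum(axis=1)
    return out
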