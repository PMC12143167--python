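"""Galerkin FEM for the steady interstitial pressure and Darcy velocity.

Discretizes the region-wise pressure equation

    -∇²P + β² (P - P_SS) = 0,        β² = (Lp·S/V + L_PL·S_L/V) / K,

(the strong form after dividing by K in each region, so interfaces carry
continuity of P and ∇P) with a zero-flux outer boundary.  The pure
Neumann problem is well posed without pinning because β² > 0 in the
viable and healthy regions anchors the solution.  Velocity is recovered
by consistent-mass L² projection of −K∇P.

An optional radial weight (|x| in the bilinear forms) turns the disc
problem into the spherically symmetric one, for validation against the
ν = 2 closed-form solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from ._fem import ElementBatch, sample_on_points
from .mesh import Mesh
from .parameters import REGION_NAMES, RegionCoefficients

__all__ = [
    "PressureSystem",
    "PressureField",
    "VelocityField",
    "assemble_pressure_system",
    "solve_pressure",
    "project_velocity",
    "flux_balance",
    "radial_pressure_profile",
]

#: convergence thresholds of the linear solves (residual, absolute, relative)
TOLERANCES = dict(residual=1e-4, absolute=1e-6, relative=1e-3)


def _coeff_list(coeffs: Dict[str, RegionCoefficients]):
    missing = [n for n in REGION_NAMES if n not in coeffs]
    if missing:
        raise ValueError(f"missing coefficients for regions: {missing}")
    return [coeffs[n] for n in REGION_NAMES]


@dataclass
class PressureSystem:
    """Assembled sparse symmetric system for the pressure unknowns."""

    mesh: Mesh
    batch: ElementBatch
    A: sparse.csr_matrix
    b: np.ndarray
    coeffs: Dict[str, RegionCoefficients]
    spherical_weight: bool = False
    k_weighted: bool = False


@dataclass
class PressureField:
    """Nodal interstitial pressure [mmHg] with solver diagnostics."""

    mesh: Mesh
    values: np.ndarray
    residual_norm: float
    iterations: int
    coeffs: Dict[str, RegionCoefficients] = field(default_factory=dict)
    batch: Optional[ElementBatch] = None

    @property
    def center(self) -> float:
        """Pressure at the node nearest the origin."""
        i = int(np.argmin(np.einsum("ij,ij->i", self.mesh.nodes,
                                    self.mesh.nodes)))
        return float(self.values[i])

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())


@dataclass
class VelocityField:
    """Nodal Darcy velocity components (U, V) [cm/s]."""

    mesh: Mesh
    values: np.ndarray  # (n_nodes, 2)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.values[:, 0], self.values[:, 1])


def assemble_pressure_system(
    mesh: Mesh,
    coeffs: Dict[str, RegionCoefficients],
    spherical_weight: bool = False,
    k_weighted: bool = False,
) -> PressureSystem:
    """Assemble stiffness ∫w∇P·∇u + ∫w β² P u and load ∫w β² P_SS u.

    ``coeffs`` maps each region name to its RegionCoefficients.  With
    ``k_weighted=True`` the conservative form ∫K∇P∇u + ∫(β²K)(P−P_SS)u is
    assembled instead (interface condition on K∇P).  ``spherical_weight``
    multiplies all integrands by the distance from the origin.
    """
    batch = ElementBatch(mesh)
    clist = _coeff_list(coeffs)
    beta2 = batch.per_element([c.beta2 for c in clist])
    pss = batch.per_element([c.PSS for c in clist])
    w_stiff = np.ones((batch.nq, batch.E))
    if k_weighted:
        w_stiff = w_stiff * batch.per_element([c.K for c in clist])
    if spherical_weight:
        r_q = np.hypot(batch.xq[..., 0], batch.xq[..., 1])
        w_stiff = w_stiff * r_q
    A = batch.stiffness(w_stiff) + batch.mass(w_stiff * beta2)
    b = batch.load(w_stiff * beta2 * pss)
    return PressureSystem(mesh=mesh, batch=batch, A=A, b=b, coeffs=coeffs,
                          spherical_weight=spherical_weight,
                          k_weighted=k_weighted)


def solve_pressure(system: PressureSystem) -> PressureField:
    """Solve the assembled system with a sparse direct factorization.

    Convergence is checked against the configured residual/absolute/
    relative thresholds; failure raises with the residual attached.
    """
    A, b = system.A, system.b
    x = spla.spsolve(A.tocsc(), b)
    res = A @ x - b
    rnorm = float(np.linalg.norm(res))
    bnorm = float(np.linalg.norm(b))
    rel = rnorm / bnorm if bnorm > 0 else rnorm
    if not np.isfinite(x).all() or (
            rnorm > TOLERANCES["residual"]
            and rel > TOLERANCES["relative"]
            and rnorm > TOLERANCES["absolute"]):
        raise RuntimeError(
            f"pressure solve did not converge: |r| = {rnorm:.3e}, "
            f"|r|/|b| = {rel:.3e}")
    return PressureField(mesh=system.mesh, values=x, residual_norm=rnorm,
                         iterations=1, coeffs=system.coeffs,
                         batch=system.batch)


def project_velocity(P: PressureField) -> VelocityField:
    """Nodal velocity from consistent-mass L² projection of −K∇P."""
    batch = P.batch or ElementBatch(P.mesh)
    clist = _coeff_list(P.coeffs)
    K_e = batch.per_element([c.K for c in clist])
    gradP = batch.grad_interpolate(P.values)        # (nq, E, 2)
    M = batch.mass().tocsc()
    lu = spla.splu(M)
    vals = np.empty((P.mesh.n_nodes, 2))
    for k in range(2):
        bk = batch.load(-K_e[None, :] * gradP[..., k])
        vals[:, k] = lu.solve(bk)
    if not np.isfinite(vals).all():
        raise RuntimeError("singular mass matrix in velocity projection")
    return VelocityField(mesh=P.mesh, values=vals)


def flux_balance(P: PressureField) -> dict:
    """Domain-integrated transvascular inflow and lymphatic outflow [cm³/s per cm].

    For the steady problem ∫φ_VS dΩ should balance ∫φ_LS dΩ up to the
    (zero-flux) boundary term and discretization error.
    """
    batch = P.batch or ElementBatch(P.mesh)
    clist = _coeff_list(P.coeffs)
    Pq = batch.interpolate(P.values)
    tag = P.mesh.region_tag
    aVS = np.array([c.phiVS_linear[0] for c in clist])[tag]
    bVS = np.array([c.phiVS_linear[1] for c in clist])[tag]
    aLS = np.array([c.phiLS_linear[0] for c in clist])[tag]
    bLS = np.array([c.phiLS_linear[1] for c in clist])[tag]
    inflow = batch.integrate(aVS[None, :] - bVS[None, :] * Pq)
    outflow = batch.integrate(aLS[None, :] + bLS[None, :] * Pq)
    return {"transvascular_in": inflow, "lymphatic_out": outflow,
            "imbalance": inflow - outflow}


def radial_pressure_profile(P: PressureField, dr: float = 1e-3) -> np.ndarray:
    """(r, P) sampled along the +x transverse line; shape (n, 2)."""
    Rht = P.mesh.geometry.Rht
    r = np.arange(0.0, Rht + dr / 2, dr)
    r = np.minimum(r, Rht * (1 - 1e-12))
    pts = np.stack([r, np.zeros_like(r)], axis=1)
    vals = sample_on_points(P.mesh, P.values, pts)
    return np.stack([r, vals], axis=1)
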