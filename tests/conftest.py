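"""Shared fixtures: parameter sets and (expensive) flow solves are session-scoped."""

import numpy as np
import pytest

from tumorflow.parameters import (
    REGION_NAMES,
    LymphaticParameters,
    TumorGeometry,
    baseline_lymphatics,
    baseline_regions,
    region_coefficients,
    vn_regions,
)
from tumorflow.mesh import build_disc_mesh
from tumorflow.fem_flow import (
    assemble_pressure_system,
    project_velocity,
    solve_pressure,
)


@pytest.fixture(scope="session")
def geom():
    return TumorGeometry()


@pytest.fixture(scope="session")
def lym0():
    """Lymphatics present but without functional dynamics (P_L = 0)."""
    return baseline_lymphatics(functional=False)


@pytest.fixture(scope="session")
def regions0():
    return baseline_regions()


@pytest.fixture(scope="session")
def coeffs0(regions0, lym0):
    return {n: region_coefficients(regions0[n], lym0) for n in REGION_NAMES}


def coeff_dict(level, functional=False, PL=-4.0):
    lym = baseline_lymphatics(functional=functional, PL=PL)
    regs = vn_regions(level)
    return regs, lym, {n: region_coefficients(regs[n], lym)
                       for n in REGION_NAMES}


@pytest.fixture(scope="session")
def mesh_h05_p2(geom):
    return build_disc_mesh(geom, 0.05, order=2)


@pytest.fixture(scope="session")
def flow_h05_p2(mesh_h05_p2, coeffs0):
    P = solve_pressure(assemble_pressure_system(mesh_h05_p2, coeffs0))
    V = project_velocity(P)
    return P, V


@pytest.fixture(scope="session")
def mesh_h01_p1(geom):
    return build_disc_mesh(geom, 0.1, order=1)


@pytest.fixture(scope="session")
def flow_h01_p1(mesh_h01_p1, coeffs0):
    P = solve_pressure(assemble_pressure_system(mesh_h01_p1, coeffs0))
    V = project_velocity(P)
    return P, V


def random_region_sets(n_sets, seed=42):
    """Physiological randomized parameter sets around the baseline."""
    import dataclasses

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sets):
        f = lambda: float(rng.uniform(0.25, 4.0))
        regs = baseline_regions()
        regs = {
            "necrotic": regs["necrotic"],
            "viable": dataclasses.replace(
                regs["viable"], Lp=regs["viable"].Lp * f(),
                K=regs["viable"].K * f(), PV=float(rng.uniform(5, 30))),
            "healthy": dataclasses.replace(
                regs["healthy"], Lp=regs["healthy"].Lp * f(),
                K=regs["healthy"].K * f(), PV=float(rng.uniform(5, 30))),
        }
        lym = LymphaticParameters(LPL_SLV=1.1e-5 * f(),
                                  PL=float(rng.uniform(-6.0, 0.0)),
                                  functional=bool(rng.integers(2)))
        out.append((regs, lym))
    return out
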