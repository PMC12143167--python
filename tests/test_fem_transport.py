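"""Transport FEM tests: conservation, closed forms, carrier behavior."""

import math

import numpy as np
import pytest
from scipy import integrate, sparse, special

from tumorflow.fem_transport import (
    HOUR,
    InjectionSpec,
    TransportOperators,
    assemble_transport_operators,
    build_initial_concentration,
    radial_profile,
    run_transport,
)
from tumorflow.parameters import (
    REGION_NAMES,
    SoluteSpec,
    carrier_spec,
    solute_from_size,
)
from tumorflow._fem import ElementBatch


def _ops_from(mesh, batch, **named):
    """TransportOperators with unspecified channels zeroed."""
    Z = sparse.csr_matrix((mesh.n_nodes, mesh.n_nodes))
    base = dict(M=batch.mass(), A=Z, Cv=Z, R_ext=Z, R_lym=Z, R_deg=Z,
                R_div=Z, solute=SoluteSpec(nr=5e-9))
    base.update(named)
    return TransportOperators(mesh=mesh, batch=batch, **base)


@pytest.fixture(scope="module")
def baseline_ops(mesh_h01_p1, flow_h01_p1, regions0, coeffs0):
    P, V = flow_h01_p1
    return assemble_transport_operators(mesh_h01_p1, P, V,
                                        solute_from_size(10.0), regions0,
                                        coeffs0)


class TestInitialCondition:
    def test_necrotic_injection_mass(self, mesh_h01_p1, geom):
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))
        batch = ElementBatch(mesh_h01_p1)
        mass = float(np.ones(mesh_h01_p1.n_nodes) @ (batch.mass() @ C0))
        lo = 4.0 * math.pi * geom.Rnt**2
        hi = 4.0 * math.pi * (geom.Rnt + mesh_h01_p1.h_max)**2
        assert lo * 0.99 <= mass <= hi

    def test_interface_nodes_take_inside_value(self, mesh_h01_p1, geom):
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))
        rn = np.hypot(*mesh_h01_p1.nodes.T)
        on_iface = np.abs(rn - geom.Rnt) < 1e-9
        assert on_iface.any() and (C0[on_iface] == 4.0).all()

    def test_ball_target_geometry(self, mesh_h01_p1):
        C0 = build_initial_concentration(
            mesh_h01_p1, InjectionSpec(target=(0.0, 0.0, 0.3), C0=4.0))
        rn = np.hypot(*mesh_h01_p1.nodes.T)
        assert (rn[C0 > 0] <= 0.3 + mesh_h01_p1.h_max).all()

    def test_target_outside_domain_raises(self, mesh_h01_p1):
        with pytest.raises(ValueError):
            build_initial_concentration(
                mesh_h01_p1, InjectionSpec(target=(5.0, 0.0, 0.1), C0=4.0))


class TestClosedForms:
    def test_pure_diffusion_conserves_mass(self, mesh_h01_p1):
        batch = ElementBatch(mesh_h01_p1)
        ops = _ops_from(mesh_h01_p1, batch, A=batch.stiffness(1e-6))
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))
        ser = run_transport(ops, C0, dt=600.0, horizon=6000.0,
                            store_times=())
        m = ser.ledger["mass"].to_numpy()
        assert np.abs(m / m[0] - 1.0).max() <= 1e-10

    def test_reaction_only_exponential_decay(self, mesh_h01_p1):
        tau = 5.8e-6
        batch = ElementBatch(mesh_h01_p1)
        ops = _ops_from(mesh_h01_p1, batch, R_deg=batch.mass(tau))
        C0 = np.full(mesh_h01_p1.n_nodes, 4.0)
        ser = run_transport(ops, C0, scheme="crank_nicolson", dt=300.0,
                            horizon=24 * HOUR, store_times=(24 * HOUR,))
        exact = 4.0 * math.exp(-tau * 24 * HOUR)
        assert ser.center_at(24 * HOUR) == pytest.approx(exact, rel=1e-4)

    def test_diffusion_matches_free_space_gaussian(self, geom):
        # a centered Gaussian spreads self-similarly before the boundary
        # is felt: C(r,t) = C0 t0/(t0+t) exp(-r²/4D(t0+t))
        from tumorflow.mesh import build_disc_mesh

        D, t0, C0v, t_end = 1e-5, 2000.0, 4.0, 600.0
        m = build_disc_mesh(geom, 0.05, order=2)
        batch = ElementBatch(m)
        ops = _ops_from(m, batch, A=batch.stiffness(D))
        rn = np.hypot(*m.nodes.T)
        C0 = C0v * np.exp(-rn**2 / (4.0 * D * t0))
        ser = run_transport(ops, C0, scheme="crank_nicolson", dt=5.0,
                            horizon=t_end, store_times=(t_end,))

        def exact(r):
            s = 4.0 * D * (t0 + t_end)
            return C0v * t0 / (t0 + t_end) * math.exp(-r**2 / s)

        snap = ser.at(t_end)
        for r in (0.0, 0.15, 0.3, 0.45, 0.6):
            i = int(np.argmin(np.abs(rn - r) + np.abs(m.nodes[:, 1])))
            assert snap[i] == pytest.approx(exact(rn[i]), rel=0.02)

    def test_schemes_agree_at_fine_step(self, baseline_ops, mesh_h01_p1):
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))
        be = run_transport(baseline_ops, C0, scheme="backward_euler",
                           dt=60.0, horizon=24 * HOUR,
                           store_times=(24 * HOUR,))
        cn = run_transport(baseline_ops, C0, scheme="crank_nicolson",
                           dt=60.0, horizon=24 * HOUR,
                           store_times=(24 * HOUR,))
        assert be.center_at(24 * HOUR) == pytest.approx(
            cn.center_at(24 * HOUR), rel=0.01)


class TestMassLedger:
    def test_ledger_closes_on_default_run(self, baseline_ops, mesh_h01_p1):
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))
        ser = run_transport(baseline_ops, C0, dt=300.0, horizon=24 * HOUR,
                            store_times=(6 * HOUR, 24 * HOUR))
        assert ser.mass_closure_error() <= 5e-3
        led = ser.ledger
        # reaction channels drain mass (tiny negative contributions can
        # arise from concentration undershoot at the injection front)
        m0 = led["mass"].iloc[0]
        for ch in ("transvascular", "lymphatic", "degradation"):
            assert led[f"cum_loss_{ch}"].iloc[-1] >= -1e-3 * m0
        assert led["mass"].iloc[-1] < led["mass"].iloc[0]

    def test_analytic_reaction_mode_is_consistent(self, mesh_h01_p1,
                                                  flow_h01_p1, regions0,
                                                  coeffs0):
        # substituting phi_VS - phi_LS for the discrete divergence changes
        # the 24-h center value only marginally
        P, V = flow_h01_p1
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))
        out = {}
        for mode in (False, True):
            ops = assemble_transport_operators(
                mesh_h01_p1, P, V, solute_from_size(10.0), regions0,
                coeffs0, analytic_reaction=mode)
            ser = run_transport(ops, C0, dt=300.0, horizon=24 * HOUR,
                                store_times=(24 * HOUR,))
            out[mode] = ser.center_at(24 * HOUR)
        assert out[True] == pytest.approx(out[False], rel=0.01)

    def test_mesh_mismatch_raises(self, geom, flow_h01_p1, regions0,
                                  coeffs0):
        from tumorflow.mesh import build_disc_mesh

        P, V = flow_h01_p1
        other = build_disc_mesh(geom, 0.2, order=1)
        with pytest.raises(ValueError):
            assemble_transport_operators(other, P, V,
                                         solute_from_size(10.0), regions0,
                                         coeffs0)


class TestCarriersAndSizes:
    def test_larger_particles_are_retained_longer(self, mesh_h01_p1,
                                                  flow_h01_p1, regions0,
                                                  coeffs0):
        P, V = flow_h01_p1
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))
        centers = []
        for size in (10.0, 100.0):
            ops = assemble_transport_operators(
                mesh_h01_p1, P, V, solute_from_size(size), regions0, coeffs0)
            ser = run_transport(ops, C0, dt=300.0, horizon=24 * HOUR,
                                store_times=(24 * HOUR,))
            centers.append(ser.center_at(24 * HOUR))
        assert centers[0] < centers[1]

    def test_doxorubicin_clears_within_hours(self, mesh_h01_p1, flow_h01_p1,
                                             regions0, coeffs0):
        P, V = flow_h01_p1
        ops = assemble_transport_operators(
            mesh_h01_p1, P, V, carrier_spec("doxorubicin"), regions0,
            coeffs0)
        C0 = build_initial_concentration(mesh_h01_p1,
                                         InjectionSpec(C0=100.0))
        ser = run_transport(ops, C0, dt=300.0, horizon=3 * HOUR,
                            store_times=(3 * HOUR,))
        assert ser.center_at(3 * HOUR) < 0.05 * 100.0

    def test_sensitivity_monotone_in_degradation_and_diffusivity(
            self, mesh_h01_p1, flow_h01_p1, regions0, coeffs0):
        P, V = flow_h01_p1
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))

        def center(tau, D):
            ss = SoluteSpec(D_override={"tumor": D, "normal": D},
                            tau_deg=tau)
            ops = assemble_transport_operators(mesh_h01_p1, P, V, ss,
                                               regions0, coeffs0)
            return run_transport(ops, C0, dt=300.0, horizon=24 * HOUR,
                                 store_times=(24 * HOUR,)
                                 ).center_at(24 * HOUR)

        grid = {(t, D): center(t, D)
                for t in (5.8e-6, 5.8e-4) for D in (4.5e-8, 4.5e-7)}
        assert grid[(5.8e-4, 4.5e-8)] <= grid[(5.8e-6, 4.5e-8)]
        assert grid[(5.8e-4, 4.5e-7)] <= grid[(5.8e-6, 4.5e-7)]
        assert grid[(5.8e-6, 4.5e-7)] <= grid[(5.8e-6, 4.5e-8)]
        assert grid[(5.8e-4, 4.5e-7)] <= grid[(5.8e-4, 4.5e-8)]


class TestProfiles:
    def test_initial_profile_is_injection_step(self, baseline_ops,
                                               mesh_h01_p1, geom):
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))
        ser = run_transport(baseline_ops, C0, dt=300.0, horizon=1 * HOUR,
                            store_times=(0.0,))
        prof = radial_profile(ser, 0.0)
        inside = prof["r_cm"] < geom.Rnt - 1e-6
        outside = prof["r_cm"] > geom.Rnt + mesh_h01_p1.h_max
        assert np.allclose(prof.loc[inside, "C_mg_cc"], 4.0, atol=1e-9)
        assert np.allclose(prof.loc[outside, "C_mg_cc"], 0.0, atol=1e-9)

    def test_profile_monotone_after_centered_injection(self, baseline_ops,
                                                       mesh_h01_p1):
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))
        ser = run_transport(baseline_ops, C0, dt=300.0, horizon=6 * HOUR,
                            store_times=(6 * HOUR,))
        prof = radial_profile(ser, 6 * HOUR)
        c = prof["C_mg_cc"].to_numpy()
        assert (np.diff(c) <= 1e-3 * c.max()).all()

    def test_profile_mass_matches_ledger(self, baseline_ops, mesh_h01_p1):
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))
        ser = run_transport(baseline_ops, C0, dt=300.0, horizon=6 * HOUR,
                            store_times=(6 * HOUR,))
        prof = radial_profile(ser, 6 * HOUR)
        r, c = prof["r_cm"].to_numpy(), prof["C_mg_cc"].to_numpy()
        mass = 2.0 * np.pi * np.trapezoid(c * r, r)
        led_mass = ser.ledger.loc[
            np.isclose(ser.ledger["time"], 6 * HOUR), "mass"].iloc[0]
        assert mass == pytest.approx(led_mass, rel=0.02)

    def test_nearest_snapshot_flagged(self, baseline_ops, mesh_h01_p1):
        C0 = build_initial_concentration(mesh_h01_p1, InjectionSpec(C0=4.0))
        ser = run_transport(baseline_ops, C0, dt=300.0, horizon=2 * HOUR,
                            store_times=(HOUR,))
        prof = radial_profile(ser, 1.5 * HOUR)
        assert prof.attrs["exact"] is False
        with pytest.raises(KeyError):
            ser.at(1.5 * HOUR)

    def test_invalid_time_grid_raises(self, baseline_ops):
        with pytest.raises(ValueError):
            run_transport(baseline_ops, np.zeros(1), dt=-1.0, horizon=10.0)
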