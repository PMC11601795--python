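"""1-D flow solver: element balances, boundary conditions, network oracles."""

import numpy as np
import pytest

from myoflow import (CouplingConfig, Simulator, attach_boundaries,
                     build_symmetric_tree)
from myoflow.errors import AssemblyError, ConfigurationError
from myoflow.experiments import SignalSpec, make_signal
from myoflow.flow_solver import (FluidProperties,
                                 characteristic_impedance, element_matrices)
from myoflow.network import VesselSpec
from myoflow.units import MMHG
from myoflow.wall_mechanics import WallGeometry


class TestElementMatrices:
    def test_hydrostatic_rest_state_has_zero_residual(self):
        """Uniform pressure, zero flow: both element rows balance exactly."""
        props = FluidProperties()
        P = np.full(2, 60.0 * MMHG)
        Q = np.zeros(2)
        A = np.full(2, 1e-4)
        C = np.full(2, 1e-10)
        es = element_matrices(P, Q, A, C, length=0.2, dt=1e-4, props=props)
        res = es.F_e @ P + es.G_e @ Q - es.h_e
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_steady_momentum_balance_is_poiseuille_drag(self):
        """At a steady state the element pressure drop equals 8 pi mu Q L / A^2."""
        props = FluidProperties()
        L, A, Q = 0.2, np.pi * (0.01) ** 2, 1e-6
        dP = 8 * np.pi * props.mu * Q * L / A**2
        P = np.asarray([50.0 * MMHG + dP, 50.0 * MMHG])
        Qv = np.full(2, Q)
        es = element_matrices(P, Qv, np.full(2, A), np.full(2, 1e-10),
                              length=L, dt=1e-4, props=props)
        res = es.F_e @ P + es.G_e @ Qv - es.h_e
        # mass row: steady pressure -> no storage; momentum row: drag balance
        np.testing.assert_allclose(res, 0.0, atol=1e-10 * dP)

    def test_rigid_mass_row_enforces_flow_uniformity(self):
        props = FluidProperties()
        P = np.asarray([60.0, 55.0]) * MMHG
        Q = np.asarray([2e-4, 3e-4])
        es = element_matrices(P, Q, np.full(2, 1e-4), np.zeros(2),
                              length=0.2, dt=1e-4, props=props)
        np.testing.assert_array_equal(es.F_e[0], 0.0)
        assert es.F_e[0] @ P + es.G_e[0] @ Q - es.h_e[0] == pytest.approx(Q[1] - Q[0])

    def test_zero_area_raises(self):
        with pytest.raises(AssemblyError):
            element_matrices(np.zeros(2), np.zeros(2), np.zeros(2),
                             np.zeros(2), 0.1, 1e-4, FluidProperties())


class TestCharacteristicImpedance:
    def test_hand_formula(self):
        A, C_A, rho = 1e-4, 1e-10, 1.04
        c = np.sqrt(A / (rho * C_A))
        assert characteristic_impedance(A, C_A, rho) == pytest.approx(rho * c / A)

    def test_doubling_area_at_fixed_wave_speed_halves_impedance(self):
        A, C_A, rho = 1e-4, 1e-10, 1.04
        z1 = characteristic_impedance(A, C_A, rho)
        # doubling A at fixed c requires doubling C_A
        z2 = characteristic_impedance(2 * A, 2 * C_A, rho)
        assert z2 == pytest.approx(z1 / 2)

    def test_nonpositive_compliance_rejected(self):
        with pytest.raises(ConfigurationError):
            characteristic_impedance(1e-4, 0.0, 1.04)


def _steady_run(topology, signal, dt=1e-4, t_end=0.05, rigid=True, **kw):
    cfg = CouplingConfig(mode="strong", dt=dt, rigid_walls=rigid)
    sim = Simulator(topology, cfg, signal, **kw)
    sim.run(t_end, sample_dt=t_end)
    return sim


class TestSteadyOracles:
    def test_no_pressure_gradient_no_flow(self, single_vessel_topology):
        signal = make_signal(SignalSpec("constant", {"level": 50.0}))
        topo = single_vessel_topology(signal, Pout=50.0, Z_mode="none")
        sim = _steady_run(topo, signal)
        np.testing.assert_allclose(sim.fluid.Q, 0.0, atol=1e-15)

    def test_single_tube_reproduces_poiseuille_flow(self, single_vessel_topology):
        """Steady flow matches Q = A^2 dP / (8 pi mu L) within 0.5%."""
        signal = make_signal(SignalSpec("constant", {"level": 52.0}))
        topo = single_vessel_topology(signal, Pout=50.0, Z_mode="none")
        sim = _steady_run(topo, signal, t_end=0.1)
        props = sim.props
        v = topo.vessels[0]
        A = sim.fluid.A[0]
        Q_exact = A**2 * 2.0 * MMHG / (8 * np.pi * props.mu * v.L)
        assert sim.fluid.Q[1] == pytest.approx(Q_exact, rel=5e-3)

    def test_rigid_tree_matches_resistor_network_solve(self, tree):
        """Steady flows in a rigid tree agree with the algebraic resistance
        network (series/parallel reduction oracle) within 0.1%."""
        topo, _ = tree
        signal = make_signal(SignalSpec("constant", {"level": 60.0}))
        topo.inlet.signal = signal
        for att in topo.outlets.values():
            att.Z, att.Z_mode = 0.0, "fixed"
        sim = _steady_run(topo, signal, t_end=0.05)
        props = sim.props

        # independent oracle: recursive series/parallel resistance reduction
        A_by_vessel = {}
        for vi, v in enumerate(topo.vessels):
            g = WallGeometry.from_load_free(v.D_o_cm, v.h_w)
            A_by_vessel[vi] = np.pi * g.Ri**2
        def R_sub(vi):
            R_own = 8 * np.pi * props.mu * topo.vessels[vi].L / A_by_vessel[vi] ** 2
            if vi in topo.junctions:
                d1, d2 = topo.junctions[vi]
                R_down = 1.0 / (1.0 / R_sub(d1) + 1.0 / R_sub(d2))
                return R_own + R_down
            return R_own
        Q_oracle = 10.0 * MMHG / R_sub(topo.root)
        assert sim.fluid.Q[topo.mid_node(0)] == pytest.approx(Q_oracle, rel=1e-3)
        # symmetric bifurcation: daughters split the parent flow evenly
        d1, d2 = topo.junctions[0]
        q1 = sim.fluid.Q[topo.first_node(d1)]
        q2 = sim.fluid.Q[topo.first_node(d2)]
        assert q1 == pytest.approx(q2, rel=1e-9)
        assert q1 + q2 == pytest.approx(sim.fluid.Q[topo.last_node(0)], rel=1e-9)

    def test_junction_mass_conservation_during_dynamic_run(self, tree):
        topo, signal = tree
        cfg = CouplingConfig(mode="weak", dt=2.5e-4, averaged_active_stress=True)
        sim = Simulator(topo, cfg, signal)
        worst = 0.0
        for _ in range(400):
            sim.advance_step()
            imbalance = sim.flow.junction_imbalance(sim.fluid.Q).max()
            worst = max(worst, imbalance / max(np.abs(sim.fluid.Q).max(), 1e-30))
        assert worst < 1e-9


class TestTemporalAccuracy:
    def test_second_order_convergence_on_smooth_problem(self, single_vessel_topology):
        """Self-convergence on a smooth compliant run: observed order >= 1.8."""
        spec = SignalSpec("periodic_variable_mean",
                          {"period": 0.05, "amplitude": 3.0, "mean_low": 60.0,
                           "mean_high": 60.0, "segment": 1.0, "t_max": 1.0})
        signal = make_signal(spec)
        t_end = 0.1

        def run(dt):
            topo = single_vessel_topology(signal, Pout=50.0)
            cfg = CouplingConfig(mode="strong", dt=dt, epsilon=1e-10,
                                 max_iters=200)
            sim = Simulator(topo, cfg, signal,
                            signalling=None)
            sim.run(t_end, sample_dt=t_end)
            return sim.fluid.Q[1]

        ref = run(1.25e-5)
        errs = [abs(run(dt) - ref) for dt in (2e-4, 1e-4, 5e-5)]
        orders = np.log2(np.asarray(errs[:-1]) / np.asarray(errs[1:]))
        assert orders.min() >= 1.8

    def test_matched_impedance_absorbs_outgoing_pulse(self, single_vessel_topology):
        """A pressure pulse reaching a characteristic-impedance terminal is
        absorbed (reflected amplitude < 5% of incident), whereas a nearly
        closed termination reflects strongly.

        Uses a mm-caliber vessel so waves propagate rather than diffuse, and
        re-matches the impedance to the wall state settled at the working
        pressure (the reference-state compliance sits in the soft toe of the
        passive curve and would mis-match the terminal).
        """
        base = 60.0
        pulse = SignalSpec("piecewise_linear",
                           {"times": [0.0, 0.100, 0.105, 0.110, 1.0],
                            "values": [base, base, base + 8.0, base, base]})
        signal = make_signal(pulse)

        def terminal_gain(z_factor):
            topo = single_vessel_topology(signal, L=4.0, D_o=3000.0, h_w=0.15,
                                          Pout=base, n_elements=40)
            cfg = CouplingConfig(mode="strong", dt=5e-5)
            sim = Simulator(topo, cfg, signal)
            sim.run(0.095, sample_dt=0.095)     # settle at working pressure
            sim.flow.set_impedances(sim.fluid.A, sim.fluid.C_A)
            sim.flow.Z = sim.flow.Z * z_factor
            sim.flow._fill_constant_rows()
            n_mid, n_term = topo.mid_node(0), topo.last_node(0)
            P_mid0, P_term0 = sim.fluid.P[n_mid], sim.fluid.P[n_term]
            peak_mid, peak_term = 0.0, 0.0
            for _ in range(round(0.08 / cfg.dt)):
                sim.advance_step()
                peak_mid = max(peak_mid, abs(sim.fluid.P[n_mid] - P_mid0))
                peak_term = max(peak_term, abs(sim.fluid.P[n_term] - P_term0))
            return peak_term / peak_mid

        matched = terminal_gain(1.0)
        blocked = terminal_gain(1e4)
        # terminal superposition of incident + reflected: gain ~ 1 + R
        assert abs(matched - 1.0) < 0.05
        assert blocked - 1.0 > 0.5


class TestAssemblyDiagnostics:
    def test_missing_outlet_is_reported(self):
        v = VesselSpec(generation="G0", L=0.4, D_o=135.0, h_w=0.3)
        topo = build_symmetric_tree(v, generations=2)
        signal = make_signal(SignalSpec("constant", {"level": 60.0}))
        attach_boundaries(topo, signal)
        del topo.outlets[topo.terminals[0]]
        with pytest.raises(ConfigurationError, match="dangling"):
            topo.validate()
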