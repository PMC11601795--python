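"""Wall mechanics: contractile system, kinematics, energies, pressure balance,
time stepping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from myoflow.errors import ConfigurationError, GeometryError
from myoflow.signalling import SignallingParams, SignallingState, step_signalling
from myoflow.units import MMHG
from myoflow.wall_mechanics import (ContractileParams,
                                    WallGeometry, WallModel, WallState,
                                    contractile_system, filament_overlap,
                                    kinematics, series_stiffness, step_wall,
                                    strain_energy, strain_energy_derivatives,
                                    transmural_pressure, wall_residuals)


class TestFilamentOverlap:
    def test_unity_at_optimum_and_symmetry(self, cp):
        assert filament_overlap(cp.u_fs_opt, cp) == 1.0
        for d in [0.005, 0.02, 0.1]:
            lo = filament_overlap(cp.u_fs_opt - d, cp)
            hi = filament_overlap(cp.u_fs_opt + d, cp)
            assert lo == pytest.approx(hi)
            assert lo < 1.0

    @given(u=st.floats(-1.0, 1.0))
    @settings(deadline=None)
    def test_never_exceeds_one(self, u):
        assert filament_overlap(u, ContractileParams()) <= 1.0


class TestContractileSystem:
    def test_no_phosphorylation_no_force(self, cp):
        Fc, Fa, ktCU, kAC = contractile_system(0.0, 0.0, 0.5, 1.2, cp)
        assert Fc == 0.0 and ktCU == 0.0 and Fa == 0.0
        assert kAC > 0.0

    def test_cortex_hill_half_activation(self, cp):
        _, _, _, kAC = contractile_system(0.0, 0.5, cp.K_AC, 1.2, cp)
        assert kAC == pytest.approx(cp.k_AC_max / 2.0)

    def test_zero_elongation_zero_reaction(self, cp):
        u = 0.013
        lam = 1.0 + 2.0 * cp.N_CU * u
        _, Fa, _, _ = contractile_system(u, 0.7, 0.6, lam, cp)
        assert Fa == pytest.approx(0.0, abs=1e-18)

    def test_series_stiffness_degenerate_convention(self):
        assert series_stiffness(0.0, 0.0) == 0.0
        assert series_stiffness(1.0, 2.0) == pytest.approx(0.5)


class TestKinematics:
    def test_inner_surface_maps_to_itself(self, geom):
        ri = 0.9 * geom.Ri
        r, _, _ = kinematics(ri, geom.Ri, geom)
        assert r == pytest.approx(ri)

    def test_identity_configuration(self):
        geom = WallGeometry(Ri=5e-3, H=1e-3)
        r, lam_r, lam_t = kinematics(geom.Ri, geom.Ri, geom)
        assert (r, lam_r, lam_t) == (pytest.approx(geom.Ri),
                                     pytest.approx(1.0), pytest.approx(1.0))

    @given(ri_fac=st.floats(0.5, 2.0), s=st.floats(0.0, 1.0),
           kw=st.floats(0.8, 1.2), lz=st.floats(0.8, 1.2))
    @settings(deadline=None)
    def test_incompressibility_holds_identically(self, ri_fac, s, kw, lz):
        geom = WallGeometry(Ri=5e-3, H=2e-3, k_omega=kw, lambda_z=lz)
        R = geom.Ri + s * geom.H
        _, lam_r, lam_t = kinematics(ri_fac * geom.Ri, R, geom)
        assert lam_r * lam_t * geom.lambda_z == pytest.approx(1.0, rel=1e-12)

    def test_negative_root_argument_raises(self, geom):
        with pytest.raises(GeometryError):
            kinematics(1e-6, 0.5 * geom.Ri, geom)


class TestStrainEnergy:
    def test_identity_stretch_zero_passive_energy(self, cp, pp):
        psi_a, psi_p = strain_energy(1.0, 1.0, 1.0, 0.0, 0.0, 0.0, cp, pp)
        assert psi_p == 0.0
        # circumferential fibres: I4 = lam_t^2 at phi = 0, so I4 = 1 here and
        # the passive derivatives carry the neo-Hookean term only
        _, dpt, dpr = strain_energy_derivatives(1.0, 1.0, 1.0, 0.0, 0.0, 0.0, cp, pp)
        assert dpt == pytest.approx(2.0 * pp.c0)
        assert dpr == pytest.approx(2.0 * pp.c0)

    @pytest.mark.parametrize("lam_t", [0.95, 1.1, 1.3])
    def test_active_derivative_matches_finite_difference(self, cp, pp, lam_t):
        """dPsi_a/dlam_t agrees with a centered difference of Psi_a."""
        u, xi5, xi7, lz = -0.015, 0.6, 0.5, 1.0
        h = 1e-6
        def psi_a(lam):
            return strain_energy(1.0 / lam, lam, lz, u, xi5, xi7, cp, pp)[0]
        fd = (psi_a(lam_t + h) - psi_a(lam_t - h)) / (2 * h)
        an, _, _ = strain_energy_derivatives(1.0 / lam_t, lam_t, lz, u, xi5, xi7, cp, pp)
        assert an == pytest.approx(fd, rel=1e-6)

    @pytest.mark.parametrize("lam_t", [1.05, 1.25])
    def test_passive_derivatives_match_finite_difference(self, cp, pp, lam_t):
        h = 1e-6
        lam_r = 0.9
        def psi_p_t(lam):
            return strain_energy(lam_r, lam, 1.0, 0.0, 0.0, 0.0, cp, pp)[1]
        def psi_p_r(lr):
            return strain_energy(lr, lam_t, 1.0, 0.0, 0.0, 0.0, cp, pp)[1]
        _, dpt, dpr = strain_energy_derivatives(lam_r, lam_t, 1.0, 0.0, 0.0, 0.0, cp, pp)
        assert dpt == pytest.approx((psi_p_t(lam_t + h) - psi_p_t(lam_t - h)) / (2 * h), rel=1e-6)
        assert dpr == pytest.approx((psi_p_r(lam_r + h) - psi_p_r(lam_r - h)) / (2 * h), rel=1e-6)

    def test_overflow_flagged_as_material_instability(self, cp, pp):
        with pytest.raises(GeometryError):
            strain_energy_derivatives(0.2, 5.0, 1.0, 0.0, 0.0, 0.0, cp, pp)

    def test_active_energy_integrates_back(self, cp, pp):
        """Quadrature of dPsi_a/dlam_t along lam_t recovers Psi_a (<= 1e-6 rel)."""
        u, xi5, xi7 = -0.015, 0.6, 0.5
        def dpsi(lam):
            return strain_energy_derivatives(1.0 / lam, lam, 1.0, u, xi5, xi7, cp, pp)[0]
        val, _ = quad(dpsi, 1.0, 1.3, epsabs=1e-14, epsrel=1e-12)
        a1 = strain_energy(1.0 / 1.3, 1.3, 1.0, u, xi5, xi7, cp, pp)[0]
        a0 = strain_energy(1.0, 1.0, 1.0, u, xi5, xi7, cp, pp)[0]
        assert val == pytest.approx(a1 - a0, rel=1e-6)


class TestTransmuralPressure:
    def test_passive_reference_state_gives_external_pressure(self, geom, cp, pp):
        A0 = np.pi * geom.Ri**2
        P = transmural_pressure(A0, np.zeros(geom.n_CL), 0.0, 0.0, geom, cp, pp)
        assert P == pytest.approx(pp.P_ext)

    def test_even_layer_count_rejected(self):
        with pytest.raises(ConfigurationError):
            WallGeometry(Ri=5e-3, H=1e-3, n_CL=4)

    @pytest.mark.parametrize("active", [False, True])
    def test_simpson_matches_fine_quadrature(self, geom, cp, pp, active):
        """5-point Simpson vs 1001-point composite quadrature within 0.5%
        over the working area range (uniform sliding across the thickness)."""
        A0 = np.pi * geom.Ri**2
        u, xi5, xi7 = (-0.015, 0.6, 0.5) if active else (0.0, 0.0, 0.0)
        fine = WallGeometry(Ri=geom.Ri, H=geom.H, n_CL=1001)
        for fac in np.linspace(0.8, 1.4, 7):
            coarse = transmural_pressure(fac * A0, np.full(geom.n_CL, u),
                                         xi5, xi7, geom, cp, pp)
            ref = transmural_pressure(fac * A0, np.full(1001, u),
                                      xi5, xi7, fine, cp, pp)
            assert coarse == pytest.approx(ref, rel=5e-3)

    def test_passive_pressure_area_curve_is_monotone(self, geom, cp, pp):
        A0 = np.pi * geom.Ri**2
        A = np.linspace(0.8, 1.4, 61) * A0
        P = transmural_pressure(A, np.zeros(geom.n_CL), 0.0, 0.0, geom, cp, pp)
        assert np.all(np.diff(P) > 0)


def _equilibrated_passive_state(wall, P_cgs):
    """Passive wall state whose area balances P_cgs exactly (for stepping tests)."""
    kern = wall.kern
    Aref = np.pi * kern.Ri[0] ** 2
    xi5 = np.zeros(wall.n_nodes)
    xi7 = np.zeros(wall.n_nodes)
    u = np.zeros((wall.n_nodes, wall.n_dyn))
    def bal(a):
        return wall.kern.pressure(np.full(wall.n_nodes, a), u, xi5, xi7,
                                  wall.averaged)[0] - P_cgs
    A_star = brentq(bal, 0.5 * Aref, 5.0 * Aref, xtol=1e-18)
    A = np.full(wall.n_nodes, A_star)
    _, lam_t, lam_dyn = kern.integrand(A, u, xi5, xi7, wall.averaged)
    return WallState(u_fs=u, lambda_theta=lam_dyn, A=A,
                     C_A=np.full(wall.n_nodes, 1e-9),
                     u_old=u.copy(), lam_old=lam_dyn.copy(), A_old=A.copy(),
                     startup=False)


class TestWallStepping:
    def test_residuals_vanish_in_static_equilibrium(self, wall):
        P = 40.0 * MMHG
        state = _equilibrated_passive_state(wall, P)
        res = wall_residuals(wall, state.u_fs, state.A, P, state,
                             np.zeros(1), np.zeros(1), dt=0.1)
        np.testing.assert_allclose(res, 0.0, atol=1e-9)

    def test_pressure_row_is_transmural_balance(self, wall, geom, cp, pp):
        state = _equilibrated_passive_state(wall, 40.0 * MMHG)
        P_bal = transmural_pressure(state.A[0], state.u_fs[0], 0.0, 0.0, geom, cp, pp)
        res = wall_residuals(wall, state.u_fs, state.A, P_bal, state,
                             np.zeros(1), np.zeros(1), dt=0.1)
        assert res[0, -1] == pytest.approx(0.0, abs=1e-9)

    def test_passive_equilibrium_persists_under_constant_pressure(self, wall):
        P = 40.0 * MMHG
        state = _equilibrated_passive_state(wall, P)
        A_start = state.A.copy()
        for _ in range(20):
            state = step_wall(P, state, np.zeros(1), np.zeros(1), wall, dt=0.5)
        np.testing.assert_allclose(state.A, A_start, rtol=1e-9)

    def test_stepper_solution_satisfies_residuals(self, wall):
        """Self-consistency: residuals at the Newton solution are tiny."""
        state = _equilibrated_passive_state(wall, 40.0 * MMHG)
        xi5, xi7 = np.full(1, 0.4), np.full(1, 0.5)
        new = wall.step(np.full(1, 55.0 * MMHG), state, xi5, xi7, dt=0.5)
        res = wall.residuals(new.u_fs, new.A, np.full(1, 55.0 * MMHG),
                             state, xi5, xi7, 0.5)
        # scale: sliding rows in 1/s, pressure row in dyn/cm^2
        assert np.abs(res[0]).max() < 1e-6
        assert abs(res[1]).max() < 1e-3 * MMHG

    def test_compliance_matches_numerical_slope_of_pressure_area_curve(self, wall):
        """Centered-difference compliance within 1% of the dA/dP of the
        passive equilibrium curve traced by an independent root solve."""
        P = 50.0 * MMHG
        state = _equilibrated_passive_state(wall, P)
        state.C_A = wall.compliance(state, np.zeros(1), np.zeros(1))
        dP = 0.5 * MMHG
        hi = _equilibrated_passive_state(wall, P + dP)
        lo = _equilibrated_passive_state(wall, P - dP)
        oracle = (hi.A[0] - lo.A[0]) / (2 * dP)
        assert state.C_A[0] == pytest.approx(oracle, rel=1e-2)

    def test_myogenic_tone_reduces_steady_area(self, geom, cp, pp):
        """Sustained 70 mmHg: steady area under control signalling is smaller
        than in the calcium-free (passive) condition."""
        areas = {}
        for mode in ("control", "zero_ca"):
            wall = WallModel(geom, cp, pp)
            params = SignallingParams().with_mode(mode)
            state = wall.initial_state()
            sig = SignallingState.zeros(1)
            for _ in range(160):  # 80 s at dt = 0.5 s
                sig = step_signalling(sig, np.full(1, 70.0), 0.5, params)
                state = wall.step(np.full(1, 70.0 * MMHG), state,
                                  sig.xi[..., 5], sig.xi7, 0.5)
            areas[mode] = state.A[0]
        assert areas["control"] < areas["zero_ca"]

    def test_averaged_variant_close_to_layer_resolved_for_thin_walls(self, cp, pp):
        """Averaged active stress vs layer-resolved: steady diameters within
        2% for H/Ri <= 0.15 across a 10-120 mmHg sweep."""
        geom = WallGeometry.from_load_free(135e-4, 0.13)
        assert geom.H / geom.Ri <= 0.15
        params = SignallingParams()
        for P in [10.0, 40.0, 70.0, 100.0, 120.0]:
            diam = {}
            for averaged in (False, True):
                wall = WallModel(geom, cp, pp, averaged=averaged)
                state = wall.initial_state()
                sig = SignallingState.zeros(1)
                for _ in range(140):
                    sig = step_signalling(sig, np.full(1, P), 0.5, params)
                    state = wall.step(np.full(1, P * MMHG), state,
                                      sig.xi[..., 5], sig.xi7, 0.5)
                diam[averaged] = wall.radii(state)[0][0]
            assert diam[True] == pytest.approx(diam[False], rel=2e-2)

    def test_incompressibility_at_every_layer_every_step(self, wall):
        state = wall.initial_state()
        sig_params = SignallingParams()
        sig = SignallingState.zeros(1)
        for P in [30.0, 60.0, 90.0]:
            sig = step_signalling(sig, np.full(1, P), 0.5, sig_params)
            state = wall.step(np.full(1, P * MMHG), state,
                              sig.xi[..., 5], sig.xi7, 0.5)
            r, lam_r, lam_t = wall.kern.stretches(state.A)
            np.testing.assert_allclose(
                lam_r * lam_t * wall.kern.lambda_z[:, None], 1.0, rtol=1e-14)


class TestGeometryConstruction:
    def test_load_free_closed_form(self):
        D_o, h_w = 135e-4, 0.30
        g = WallGeometry.from_load_free(D_o, h_w)
        r_mean = g.Ri + g.H / 2
        assert g.H / r_mean == pytest.approx(h_w)
        assert 2 * (g.Ri + g.H) == pytest.approx(D_o)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            WallGeometry(Ri=-1.0, H=1e-3)
        with pytest.raises(ConfigurationError):
            WallGeometry.from_load_free(135e-4, 1.5)
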