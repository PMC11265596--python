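"""Nanobubble thermodynamics and Rayleigh-Plesset dynamics."""
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import normaltest

from xylembubbles import (
    GammaCurve,
    GasState,
    KelvinInput,
    RPParams,
    classify_regime,
    cnt_barrier,
    critical_radii,
    dG_dr,
    integrate_rp,
    internal_pressure,
    kelvin_potential,
    laplace_dp,
    study_gamma_curve,
    viscosity,
)
from xylembubbles.bubble import (
    EMBOLISM,
    EQUILIBRATION,
    GROWTH,
    BubbleTrajectory,
    _rp_rhs_factory,
    thermal_noise_amplitude,
)
from xylembubbles.constants import NM_TO_M


class TestKelvinPotential:
    def test_saturated_air_gives_zero(self):
        assert kelvin_potential(KelvinInput(a_w=1.0, temperature=298.0)) == 0.0

    def test_hand_evaluated_case(self):
        # (kB * 298 / 2.99e-29) * ln(0.98) = -2.78 MPa
        psi = kelvin_potential(KelvinInput(a_w=0.98, temperature=298.0))
        assert psi == pytest.approx(-2.78e6, rel=1e-2)

    def test_strictly_decreasing_in_drying_air(self):
        psis = [kelvin_potential(KelvinInput(a_w=a, temperature=298.0)) for a in (0.99, 0.95, 0.9)]
        assert psis[0] > psis[1] > psis[2]

    def test_invalid_activity_rejected(self):
        with pytest.raises(ValueError):
            kelvin_potential(KelvinInput(a_w=0.0, temperature=298.0))


class TestLaplaceAndInternalPressure:
    def test_xylem_tension_range(self):
        # bulk sap surface tensions 45-68 mN/m on a 50 nm bubble
        assert laplace_dp(45.0, 50.0) == pytest.approx(1.8)
        assert laplace_dp(68.0, 50.0) == pytest.approx(2.72)

    def test_water_potential_lowers_internal_pressure(self):
        assert internal_pressure(45.0, 50.0, -1.0) == pytest.approx(0.8)
        assert internal_pressure(68.0, 50.0, -1.0) == pytest.approx(1.72)

    def test_zero_potential_reduces_to_laplace(self):
        assert internal_pressure(55.0, 60.0, 0.0) == laplace_dp(55.0, 60.0)

    def test_zero_tension_and_bad_radius(self):
        assert laplace_dp(0.0, 50.0) == 0.0
        with pytest.raises(ValueError):
            laplace_dp(45.0, 0.0)


class TestCntBarrier:
    def test_hand_evaluated_barrier(self):
        b = cnt_barrier(70.5, -2.0)
        assert b.r_cavitation == pytest.approx(70.5, rel=1e-12)
        assert b.delta_g == pytest.approx(16 * math.pi * 0.0705**3 / (3 * (2e6) ** 2), rel=1e-12)

    def test_algebraic_identity_with_area_term(self):
        for gamma, p in ((45.0, -1.0), (70.5, -2.5), (30.0, -0.3)):
            b = cnt_barrier(gamma, p)
            ident = (4 * math.pi / 3) * (gamma * 1e-3) * (b.r_cavitation * 1e-9) ** 2
            assert b.delta_g == pytest.approx(ident, rel=1e-12)

    def test_quadratic_pressure_scaling(self):
        assert cnt_barrier(70.5, -4.0).delta_g == pytest.approx(cnt_barrier(70.5, -2.0).delta_g / 4)

    def test_positive_pressure_rejected(self):
        with pytest.raises(ValueError):
            cnt_barrier(70.5, 1.0)


class TestViscosity:
    def test_printed_anchors(self):
        assert viscosity(270.0) == pytest.approx(2.00e-3, rel=1e-3)
        assert viscosity(310.0) == pytest.approx(0.69e-3, rel=1e-3)

    def test_strictly_decreasing_on_validity_range(self):
        ts = np.linspace(240.0, 370.0, 60)
        etas = np.array([viscosity(t) for t in ts])
        assert np.all(np.diff(etas) < 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            viscosity(200.0)
        with pytest.raises(ValueError):
            viscosity(380.0)


class TestFreeEnergySlope:
    def test_static_gamma_no_gas_root_is_laplace_radius(self):
        """dG/dr vanishes exactly at r = 2 gamma / |p| (machine precision)."""
        curve = GammaCurve.constant(70.5, domain=(10.0, 500.0))
        r_lap = 2 * 70.5 / 1.5  # nm, = 2 gamma/|p| with the mN/m / nm / MPa convention
        # term magnitude is ~1e-7 J/m; 1e-20 is machine-precision cancellation
        assert dG_dr(r_lap, curve, -1.5) == pytest.approx(0.0, abs=1e-20)
        # and it is the CNT stationary point
        assert cnt_barrier(70.5, -1.5).r_cavitation == pytest.approx(r_lap, rel=1e-12)

    def test_static_gamma_with_gas_root_matches_bisection(self):
        curve = GammaCurve.constant(70.5, domain=(10.0, 500.0))
        gas = GasState(p_ref=1.6, r_ref=66.0, kappa=1.4)

        def balance(r):  # p_gas(r) - p - 2 gamma / r, MPa
            return gas.pressure(r) - (-0.5) - laplace_dp(70.5, r)

        root = brentq(balance, 20.0, 100.0, xtol=1e-12)
        assert dG_dr(root, curve, -0.5, gas) == pytest.approx(0.0, abs=1e-18)

    def test_all_sign_changes_found_by_dense_scan(self):
        curve = study_gamma_curve(270.0)
        gas = GasState(p_ref=1.0, r_ref=45.0)
        cr = critical_radii(curve, -1.5, gas)
        rs = np.linspace(20.0, 700.0, 200_001)
        vals = dG_dr(rs, curve, -1.5, gas)
        flips = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
        assert len(flips) == len(cr.roots)
        for i, (root, _) in zip(flips, sorted(cr.roots)):
            assert rs[i] <= root <= rs[i + 1]
        for root, _ in cr.roots:
            assert abs(dG_dr(root, curve, -1.5, gas)) < 1e-9 * abs(dG_dr(1.5 * root, curve, -1.5, gas))


class TestCriticalRadii:
    def test_static_curve_gives_only_the_laplace_root(self):
        curve = GammaCurve.constant(70.5, domain=(10.0, 500.0))
        cr = critical_radii(curve, -1.5, gas_state=None)
        assert cr.r_crit is None and cr.r_eq is None
        assert len(cr.roots) == 1
        assert cr.roots[0][0] == pytest.approx(2 * 70.5 / 1.5, rel=1e-9)
        assert cr.roots[0][1] == "unstable"

    def test_sigmoid_curve_yields_ordered_stable_unstable_pair(self):
        curve = study_gamma_curve(270.0)
        cr = critical_radii(curve, -1.5, GasState(p_ref=1.0, r_ref=45.0))
        assert cr.r_eq is not None and cr.r_crit is not None
        assert cr.r_eq < cr.r_crit
        for r in (cr.r_eq, cr.r_crit):
            # ~1e-8 relative to the 1e-7 J/m scale of the individual terms
            assert abs(dG_dr(r, curve, -1.5, GasState(p_ref=1.0, r_ref=45.0))) < 1e-15

    def test_r_crit_shrinks_then_vanishes_under_deeper_tension(self):
        """The coating-induced embolism threshold closes as |p| grows."""
        curve = study_gamma_curve(270.0)
        gas = GasState(p_ref=1.0, r_ref=45.0)
        crits = []
        for p in (-0.5, -1.0, -1.5, -2.0, -2.5):
            crits.append(critical_radii(curve, p, gas).r_crit)
        present = [c for c in crits if c is not None]
        assert all(a >= b for a, b in zip(present, present[1:]))
        # window closes at the most negative pressures, never reopens
        closed = [c is None for c in crits]
        assert closed == sorted(closed)
        assert closed[-1]


class TestIntegration:
    @staticmethod
    def _static_setup(p_mpa=-0.5, r0=66.0):
        curve = GammaCurve.constant(70.5, domain=(20.0, 400.0))
        params = RPParams(p_liquid=p_mpa * 1e6, temperature=270.0, r0=r0, t_end=100.0)
        _, pbal, pgas0 = _rp_rhs_factory(params, curve)
        rs = np.geomspace(20.0, 400.0, 4000)
        vals = np.array([pbal(r * NM_TO_M, 0.0) for r in rs])
        flips = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
        roots = [
            brentq(lambda r: pbal(r * NM_TO_M, 0.0), rs[i], rs[i + 1], xtol=1e-13)
            for i in flips
        ]
        return curve, params, pgas0, roots

    def test_fixed_point_is_stationary_for_100ns(self):
        curve, params, pgas0, roots = self._static_setup()
        r_eq = roots[0]
        p2 = RPParams(
            p_liquid=params.p_liquid, temperature=270.0, r0=r_eq,
            p_gas0=pgas0, gas_r_ref=66.0, t_end=100.0,
        )
        traj = integrate_rp(p2, curve)
        assert traj.times[-1] == pytest.approx(100.0)
        assert np.max(np.abs(traj.radii - r_eq)) / r_eq < 1e-3

    def test_damped_oscillation_converges_to_bisected_balance(self):
        curve, params, pgas0, roots = self._static_setup()
        r_eq = roots[0]
        p3 = RPParams(
            p_liquid=params.p_liquid, temperature=270.0, r0=0.85 * r_eq,
            p_gas0=pgas0, gas_r_ref=66.0, t_end=100.0,
        )
        traj = integrate_rp(p3, curve)
        assert abs(traj.radii[-1] - r_eq) / r_eq < 1e-3

    def test_mechanical_energy_decays_between_oscillation_peaks(self):
        curve, params, pgas0, roots = self._static_setup()
        r_eq = roots[0]
        p3 = RPParams(
            p_liquid=params.p_liquid, temperature=270.0, r0=0.8 * r_eq,
            p_gas0=pgas0, gas_r_ref=66.0, t_end=30.0,
        )
        traj = integrate_rp(p3, curve)
        gas = GasState(p_ref=pgas0 / 1e6, r_ref=66.0, kappa=1.4)
        rho = 1000.0

        def g_of(r_nm):
            """G(r) - G(r_eq) by quadrature of the analytic slope."""
            val, _ = quad(lambda r: dG_dr(r, curve, params.p_liquid / 1e6, gas), r_eq, r_nm)
            return val * 1e-9  # integral over nm of J/m

        # oscillation peaks = velocity zero crossings; energy there is potential
        sgn = np.sign(traj.velocities)
        peaks = np.where(sgn[:-1] * sgn[1:] < 0)[0][:6]
        assert len(peaks) >= 3
        r_si = traj.radii[peaks] * NM_TO_M
        v_si = traj.velocities[peaks]  # nm/ns is numerically m/s
        peak_e = 2 * math.pi * rho * r_si**3 * v_si**2 + np.array(
            [g_of(r) for r in traj.radii[peaks]]
        )
        assert np.all(np.diff(peak_e) < 1e-22)

    def test_noise_off_is_seed_independent(self):
        curve = study_gamma_curve(270.0)
        base = dict(p_liquid=-1.5e6, temperature=270.0, r0=80.0, p_gas0=1.0e6,
                    gas_r_ref=45.0, t_end=5.0)
        a = integrate_rp(RPParams(seed=1, **base), curve)
        b = integrate_rp(RPParams(seed=99, **base), curve)
        assert np.array_equal(a.radii, b.radii)

    def test_noise_on_is_seed_reproducible_and_fluctuates(self):
        curve = study_gamma_curve(270.0)
        base = dict(p_liquid=-1.5e6, temperature=270.0, r0=80.0, p_gas0=1.0e6,
                    gas_r_ref=45.0, t_end=2.0, noise_enabled=True)
        a = integrate_rp(RPParams(seed=5, **base), curve)
        b = integrate_rp(RPParams(seed=5, **base), curve)
        c = integrate_rp(RPParams(seed=6, **base), curve)
        assert np.array_equal(a.radii, b.radii)
        assert not np.array_equal(a.radii, c.radii)

    def test_noise_kicks_are_gaussian_with_configured_variance(self):
        """Velocity increments of the pure noise process match the set amplitude."""
        rho, dt, r = 1000.0, 10e-12, 80e-9
        amp = thermal_noise_amplitude(80.0, 270.0, viscosity(270.0))
        kicks = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            kicks.extend(amp * math.sqrt(dt) * rng.standard_normal(500) / (rho * r))
        kicks = np.array(kicks)
        _, pval = normaltest(kicks)
        assert pval > 0.01
        expected_sd = amp * math.sqrt(dt) / (rho * r)
        assert np.std(kicks) == pytest.approx(expected_sd, rel=0.05)


class TestRegimes:
    @pytest.fixture(scope="class")
    def study(self):
        curve = study_gamma_curve(270.0)
        gas = GasState(p_ref=1.0, r_ref=45.0, kappa=1.4)
        cr = critical_radii(curve, -1.5, gas)
        return curve, gas, cr

    def test_three_regimes_by_injection_radius(self, study):
        curve, gas, cr = study
        cases = {
            45.0: GROWTH,
            0.5 * (cr.r_eq + cr.r_crit): EQUILIBRATION,
            1.15 * cr.r_crit: EMBOLISM,
        }
        for r0, want in cases.items():
            params = RPParams(
                p_liquid=-1.5e6, temperature=270.0, r0=r0,
                p_gas0=gas.p_ref * 1e6, gas_r_ref=gas.r_ref, t_end=100.0,
            )
            traj = integrate_rp(params, curve)
            assert classify_regime(traj, (cr.r_eq, cr.r_crit)) == want, traj.diagnostics

    def test_equilibration_window_is_a_closing_interval(self, study):
        curve, gas, _ = study
        stable = []
        for p in (-0.5, -1.0, -1.5, -2.0, -2.5):
            cr = critical_radii(curve, p, gas)
            stable.append(cr.r_eq is not None)
        # equilibration pressures form a prefix of the scan and the window closes
        assert stable == sorted(stable, reverse=True)
        assert stable[0] and not stable[-1]

    def test_no_stable_root_means_embolism_from_r0_45(self, study):
        curve, gas, _ = study
        cr = critical_radii(curve, -2.5, gas)
        assert cr.r_eq is None
        params = RPParams(
            p_liquid=-2.5e6, temperature=270.0, r0=45.0,
            p_gas0=gas.p_ref * 1e6, gas_r_ref=gas.r_ref, t_end=200.0,
        )
        traj = integrate_rp(params, curve)
        assert classify_regime(traj, (cr.r_eq, cr.r_crit)) == EMBOLISM


class TestClassifyRegime:
    def test_constant_trajectory_at_equilibrium(self):
        t = np.linspace(0, 10, 101)
        traj = BubbleTrajectory(times=t, radii=np.full_like(t, 70.0), velocities=np.zeros_like(t))
        assert classify_regime(traj, (70.0, 120.0)) == EQUILIBRATION

    def test_monotone_divergence_is_embolism(self):
        t = np.linspace(0, 10, 101)
        traj = BubbleTrajectory(times=t, radii=130.0 + 20 * t, velocities=np.full_like(t, 20.0))
        assert classify_regime(traj, (70.0, 120.0)) == EMBOLISM

    def test_damped_cosine_is_equilibration(self):
        t = np.linspace(0, 10, 1001)
        r = 70.0 + 5.0 * np.exp(-t) * np.cos(8 * t)
        v = np.gradient(r, t)
        traj = BubbleTrajectory(times=t, radii=r, velocities=v)
        assert classify_regime(traj, (70.0, 120.0)) == EQUILIBRATION

    def test_growth_from_below(self):
        t = np.linspace(0, 10, 1001)
        r = 70.0 - 30.0 * np.exp(-t)
        v = np.gradient(r, t)
        traj = BubbleTrajectory(times=t, radii=r, velocities=v)
        assert classify_regime(traj, (70.0, 120.0)) == GROWTH
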