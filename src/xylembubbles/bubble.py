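"""Thermodynamics and dynamics of a lipid-coated nanobubble under negative pressure.

A gas nanobubble in stretched sap water sits on a free-energy surface G(r)
whose slope, obtained by differentiating the Gibbs free energy of a bubble
of radius r carrying a fixed lipid coating, is

    dG/dr = 8 pi r gamma(r) + 4 pi r^2 dgamma/dr + 4 pi r^2 (p - p_gas(r)),

with p the (negative) liquid pressure and p_gas(r) = p_gas0 (r0/r)^(3 kappa)
the polytropic internal gas pressure.  In the static-tension limit
(dgamma/dr = 0) the stationary points reduce to the Laplace balance
p_gas - p = 2 gamma / r, and with no gas one recovers the classical
nucleation theory stationary point r = 2 gamma / |p| with barrier
Delta G* = 16 pi gamma^3 / (3 p^2).  Because the lipid film makes gamma a
function of r, a second, coating-induced critical radius appears: a stable
equilibrium r_eq and an unstable threshold r_crit above which growth runs
away into an embolism.

The time evolution follows the modified Rayleigh-Plesset equation

    rho (r r'' + 3/2 r'^2) = p_gas0 (r0/r)^(3 kappa) - p
                             - (2 gamma(r)/r) (1 - delta/r)
                             - dgamma/dr - 4 eta r'/r  [+ noise],

where delta is the Tolman length (first-order curvature correction to
gamma, applied multiplicatively on the Laplace term), eta the liquid
viscosity and rho its density.  Optional thermal noise enters as a
Gaussian stochastic pressure with a fluctuation-dissipation-consistent
default amplitude for the 4 eta r'/r friction.  The ODE is integrated in SI
units with a stiff implicit multistep (BDF) scheme on a fixed output grid.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .constants import K_B, MN_PER_M_TO_SI, MPA_TO_PA, NM_TO_M, NS_TO_S, PS_TO_S, RHO_WATER, V_M_WATER
from .tension import GammaCurve

__all__ = [
    "KelvinInput",
    "GasState",
    "RPParams",
    "BubbleTrajectory",
    "CriticalRadii",
    "CntBarrier",
    "kelvin_potential",
    "laplace_dp",
    "internal_pressure",
    "cnt_barrier",
    "viscosity",
    "dG_dr",
    "critical_radii",
    "thermal_noise_amplitude",
    "integrate_rp",
    "classify_regime",
]

GROWTH = "growth"
EQUILIBRATION = "equilibration"
EMBOLISM = "embolism"
DISSOLUTION = "dissolution"
AMBIGUOUS = "ambiguous"


# --------------------------------------------------------------------------
# equilibrium thermodynamics
# --------------------------------------------------------------------------

@dataclass
class KelvinInput:
    """Inputs of the Kelvin water-potential relation."""

    a_w: float  # relative humidity / water activity, (0, 1]
    temperature: float  # K
    v_m: float = V_M_WATER  # molecular volume of water, m^3
    k_b: float = K_B  # J/K


def kelvin_potential(inp: KelvinInput) -> float:
    """Water potential Psi = (k_B T / v_m) ln(a_w), in Pa (<= 0 for a_w <= 1).

    This is the negative pressure generated by evaporation against an
    ambient relative humidity a_w directly below a stoma.
    """
    if not 0.0 < inp.a_w <= 1.0:
        raise ValueError(f"water activity must lie in (0, 1], got {inp.a_w}")
    return inp.k_b * inp.temperature / inp.v_m * math.log(inp.a_w)


def laplace_dp(gamma: float, r: float) -> float:
    """Laplace pressure differential 2 gamma / r in MPa (gamma mN/m, r nm).

    1 mN/m per nm is exactly 1 MPa, so the numerical form is simply 2*gamma/r.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    return 2.0 * gamma / r


def internal_pressure(gamma: float, r: float, psi_water: float) -> float:
    """Equilibrium internal gas pressure 2 gamma / r + Psi_water, MPa.

    A negative surrounding water potential lowers, rather than raises, the
    pressure the bubble interior must sustain at mechanical equilibrium.
    """
    return laplace_dp(gamma, r) + psi_water


@dataclass
class CntBarrier:
    r_cavitation: float  # nm
    delta_g: float  # J
    delta_g_kt: Optional[float]  # units of k_B T, if a temperature was given


def cnt_barrier(gamma: float, p_liquid: float, temperature: Optional[float] = None) -> CntBarrier:
    """Classical nucleation theory cavitation barrier for a void in stretched water.

    gamma in mN/m, p_liquid in MPa (must be negative).  Returns the critical
    cavitation radius r = 2 gamma / |p| (nm) and the barrier height
    Delta G* = 16 pi gamma^3 / (3 p^2) (J, and k_B T if T given).
    """
    if p_liquid >= 0:
        raise ValueError("cavitation barrier requires a negative liquid pressure")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    g_si = gamma * MN_PER_M_TO_SI
    p_si = p_liquid * MPA_TO_PA
    r_cav = 2.0 * g_si / abs(p_si) / NM_TO_M
    dg = 16.0 * math.pi * g_si**3 / (3.0 * p_si**2)
    dg_kt = dg / (K_B * temperature) if temperature is not None else None
    return CntBarrier(r_cavitation=r_cav, delta_g=dg, delta_g_kt=dg_kt)


# --------------------------------------------------------------------------
# viscosity of (supercooled) water
# --------------------------------------------------------------------------

#: Singular temperature of the supercooled-water power law, K.
_VISC_TS = 225.66
# eta = eta0 * (T/Ts - 1)^(-g); eta0 and g solved exactly from the two
# anchors eta(270 K) = 2.00e-3 and eta(310 K) = 0.69e-3 Pa s.
_X270 = 270.0 / _VISC_TS - 1.0
_X310 = 310.0 / _VISC_TS - 1.0
_VISC_G = math.log(2.00e-3 / 0.69e-3) / math.log(_X310 / _X270)
_VISC_ETA0 = 2.00e-3 * _X270**_VISC_G


def viscosity(temperature: float) -> float:
    """Viscosity of water in Pa s from a supercooled-water power law.

    eta(T) = eta0 (T/T_s - 1)^(-g) with T_s = 225.66 K; eta0 and g are fixed
    by the anchors eta(270 K) = 2.00e-3 and eta(310 K) = 0.69e-3 Pa s.
    Valid for 239 K < T < 373 K.
    """
    if not 239.0 < temperature < 373.0:
        raise ValueError(f"viscosity parameterisation valid for 239-373 K, got {temperature}")
    return _VISC_ETA0 * (temperature / _VISC_TS - 1.0) ** (-_VISC_G)


# --------------------------------------------------------------------------
# free-energy landscape
# --------------------------------------------------------------------------

@dataclass
class GasState:
    """Polytropic gas load of the bubble: p_gas(r) = p_ref (r_ref / r)^(3 kappa)."""

    p_ref: float  # MPa, internal gas pressure at r_ref
    r_ref: float  # nm
    kappa: float = 1.4

    def __post_init__(self) -> None:
        if self.r_ref <= 0 or self.kappa <= 0:
            raise ValueError("r_ref and kappa must be positive")

    def pressure(self, r) -> np.ndarray:
        """Internal gas pressure at radius r (nm), MPa."""
        r = np.asarray(r, dtype=float)
        out = self.p_ref * (self.r_ref / r) ** (3.0 * self.kappa)
        return float(out) if out.ndim == 0 else out


def dG_dr(r, curve: GammaCurve, p_liquid: float, gas_state: Optional[GasState] = None):
    """Slope of the bubble Gibbs free energy at radius r (nm), in J/m.

    dG/dr = 8 pi r gamma(r) + 4 pi r^2 dgamma/dr + 4 pi r^2 (p - p_gas(r)),
    with p_liquid in MPa.  Roots are mechanical force balances: in the
    static-gamma limit they satisfy the Laplace equation, and without gas
    they reproduce the classical nucleation theory stationary point.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    r_si = r * NM_TO_M
    g_si = np.asarray(curve.gamma(r)) * MN_PER_M_TO_SI
    dg_si = np.asarray(curve.dgamma_dr(r)) * MN_PER_M_TO_SI / NM_TO_M
    p_si = p_liquid * MPA_TO_PA
    pgas_si = (np.asarray(gas_state.pressure(r)) * MPA_TO_PA) if gas_state is not None else 0.0
    out = (
        8.0 * np.pi * r_si * g_si
        + 4.0 * np.pi * r_si**2 * dg_si
        + 4.0 * np.pi * r_si**2 * (p_si - pgas_si)
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class CriticalRadii:
    """Stationary radii of the coated-bubble free energy at one liquid pressure.

    r_eq is the stable equilibrium (minimum of G), r_crit the unstable
    embolism threshold above it (maximum of G, present only because
    dgamma/dr != 0), and r_cavitation the bare CNT radius computed from the
    curve's large-r plateau tension.  Missing roots are None, with the scan
    diagnostic preserved.
    """

    r_eq: Optional[float]
    r_crit: Optional[float]
    r_cavitation: Optional[float]
    roots: List[Tuple[float, str]] = field(default_factory=list)  # (r, "stable"/"unstable")
    diagnostic: str = ""


def critical_radii(
    curve: GammaCurve,
    p_liquid: float,
    gas_state: Optional[GasState] = None,
    *,
    n_scan: int = 4000,
    scan_range: Optional[Tuple[float, float]] = None,
) -> CriticalRadii:
    """Locate and classify the stationary radii of G(r).

    Sign changes of dG/dr on a log-spaced scan are polished by bisection
    (brentq).  A root where dG/dr crosses from negative to positive is a
    minimum of G (stable); positive to negative is a maximum (unstable).
    """
    lo, hi = scan_range if scan_range is not None else (0.3 * curve.domain[0], 5.0 * curve.domain[1])
    rs = np.geomspace(lo, hi, n_scan)
    vals = np.asarray(dG_dr(rs, curve, p_liquid, gas_state))
    roots: List[Tuple[float, str]] = []
    f = lambda r: dG_dr(r, curve, p_liquid, gas_state)
    for i in range(len(rs) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append((float(rs[i]), "stable" if (i + 1 < len(rs) and vals[i + 1] > 0) else "unstable"))
        elif a * b < 0:
            root = brentq(f, rs[i], rs[i + 1], xtol=1e-12, rtol=1e-14)
            roots.append((float(root), "stable" if a < 0 else "unstable"))
    stable = [r for r, kind in roots if kind == "stable"]
    unstable = [r for r, kind in roots if kind == "unstable"]
    r_eq = min(stable) if stable else None
    r_crit = None
    if r_eq is not None:
        above = [r for r in unstable if r > r_eq]
        # the embolism threshold is the outermost barrier: beyond it growth
        # runs away (dG/dr < 0 as r -> inf under tension, so the last root is
        # unstable); small-amplitude wiggles of a fitted curve may insert
        # spurious stable/unstable pairs below it
        r_crit = max(above) if above else None
    gamma_plateau = curve.plateaus()[1]
    r_cav = None
    if p_liquid < 0 and gamma_plateau > 0:
        r_cav = cnt_barrier(gamma_plateau, p_liquid).r_cavitation
    diag = "" if roots else (
        f"no stationary radius of dG/dr in [{lo:.3g}, {hi:.3g}] nm at p = {p_liquid} MPa "
        "(extreme-negative-pressure regime: every bubble in range grows or shrinks monotonically)"
    )
    return CriticalRadii(r_eq=r_eq, r_crit=r_crit, r_cavitation=r_cav, roots=roots, diagnostic=diag)


# --------------------------------------------------------------------------
# Rayleigh-Plesset integration
# --------------------------------------------------------------------------

@dataclass
class RPParams:
    """Parameters of the modified Rayleigh-Plesset integration.

    Pressures in Pa, radii in nm, dt in ps, t_end in ns (converted to SI
    internally).  ``p_gas0`` defaults to the Laplace-balanced internal
    pressure at the injection radius, 2 gamma(r0)/r0 + p_liquid (clamped at
    zero if the balance is negative, i.e. an effectively gas-free bubble).
    ``gas_r_ref`` decouples the gas load from the injection radius when
    several injection radii share one gas content.
    """

    p_liquid: float  # Pa (negative under tension)
    temperature: float  # K
    r0: float  # nm, injection radius
    p_gas0: Optional[float] = None  # Pa at gas_r_ref (default: Laplace-balanced at r0)
    gas_r_ref: Optional[float] = None  # nm (default: r0)
    kappa: float = 1.4
    delta_tolman: float = 0.0316  # nm, positive per the negative-pressure bubble convention
    eta: Optional[float] = None  # Pa s (default: viscosity(temperature))
    rho_liquid: float = RHO_WATER  # kg/m^3
    n_lipids: float = 1e5
    v0: float = 0.0  # nm/ns, initial radial velocity
    dt: float = 10.0  # ps, output timestep
    t_end: float = 100.0  # ns
    noise_enabled: bool = False
    noise_amplitude: Optional[float] = None  # Pa sqrt(s); default fluctuation-dissipation
    seed: int = 0
    r_min: float = 1.0  # nm, dissolution cutoff
    r_max: Optional[float] = None  # nm (default 10x the curve's largest fitted radius)

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.rho_liquid <= 0 or self.dt <= 0 or self.r0 <= 0:
            raise ValueError("kappa, rho_liquid, dt and r0 must be positive")
        if self.eta is None:
            self.eta = viscosity(self.temperature)
        if self.eta <= 0:
            raise ValueError("eta must be positive")


@dataclass
class BubbleTrajectory:
    times: np.ndarray  # ns
    radii: np.ndarray  # nm
    velocities: np.ndarray  # nm/ns
    regime: str = AMBIGUOUS
    terminated: Optional[str] = None  # "dissolution" / "embolism" / None
    r_eq: Optional[float] = None
    r_crit: Optional[float] = None
    r_cavitation: Optional[float] = None
    diagnostics: str = ""


def thermal_noise_amplitude(r_nm: float, temperature: float, eta: float) -> float:
    """Fluctuation-dissipation stochastic pressure amplitude, Pa sqrt(s).

    The RP friction force is 16 pi eta r rdot (the 4 eta rdot / r pressure
    term times 4 pi r^2), so the Langevin force amplitude is
    sqrt(2 k_B T * 16 pi eta r); divided by the bubble area this is a
    stochastic pressure of spectral amplitude sqrt(2 k_B T eta / (pi r^3)).
    """
    r = r_nm * NM_TO_M
    return math.sqrt(2.0 * K_B * temperature * eta / (math.pi * r**3))


def _rp_rhs_factory(params: RPParams, curve: GammaCurve) -> Callable:
    rho = params.rho_liquid
    p = params.p_liquid
    delta = params.delta_tolman * NM_TO_M
    eta = params.eta
    kappa = params.kappa
    r_ref = (params.gas_r_ref if params.gas_r_ref is not None else params.r0) * NM_TO_M
    if params.p_gas0 is not None:
        p_gas0 = params.p_gas0
    else:
        g0 = curve.gamma(params.r0) * MN_PER_M_TO_SI
        p_gas0 = 2.0 * g0 / (params.r0 * NM_TO_M) + p
        if p_gas0 < 0:
            warnings.warn(
                "Laplace-balanced default p_gas0 is negative at r0; clamped to 0 (gas-free)",
                stacklevel=3,
            )
            p_gas0 = 0.0

    def pressure_balance(r_si: float, v_si: float) -> float:
        """RHS of the RP pressure balance at (r, rdot), Pa."""
        r_nm = r_si / NM_TO_M
        g = curve.gamma(r_nm) * MN_PER_M_TO_SI
        dg = curve.dgamma_dr(r_nm) * MN_PER_M_TO_SI / NM_TO_M
        p_gas = p_gas0 * (r_ref / r_si) ** (3.0 * kappa) if p_gas0 != 0.0 else 0.0
        return (
            p_gas
            - p
            - (2.0 * g / r_si) * (1.0 - delta / r_si)
            - dg
            - 4.0 * eta * v_si / r_si
        )

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        r, v = y
        pb = pressure_balance(r, v)
        acc = (pb - 1.5 * rho * v * v) / (rho * r)
        return np.array([v, acc])

    return rhs, pressure_balance, p_gas0


def integrate_rp(params: RPParams, curve: GammaCurve) -> BubbleTrajectory:
    """Integrate the modified Rayleigh-Plesset equation on a fixed output grid.

    Deterministic runs use a single stiff BDF solve with terminal events at
    the dissolution (r_min) and embolism (r_max) bounds.  With thermal noise
    enabled, the deterministic dynamics are advanced BDF-step by step over
    each output interval and a seeded Gaussian velocity kick with the
    configured stochastic-pressure amplitude is added per step
    (Euler-Maruyama splitting).
    """
    rhs, _, _ = _rp_rhs_factory(params, curve)
    r0 = params.r0 * NM_TO_M
    v0 = params.v0 * NM_TO_M / NS_TO_S
    t_end = params.t_end * NS_TO_S
    dt = params.dt * PS_TO_S
    r_min = params.r_min * NM_TO_M
    r_max = (params.r_max if params.r_max is not None else 10.0 * curve.domain[1]) * NM_TO_M
    t_eval = np.arange(0.0, t_end + dt / 2, dt)

    def ev_min(t, y):
        return y[0] - r_min

    def ev_max(t, y):
        return y[0] - r_max

    ev_min.terminal, ev_min.direction = True, -1
    ev_max.terminal, ev_max.direction = True, 1

    atol = np.array([1e-13, 1e-5])
    if not params.noise_enabled:
        sol = solve_ivp(
            rhs, (0.0, t_end), [r0, v0], method="BDF", t_eval=t_eval,
            events=[ev_min, ev_max], rtol=1e-8, atol=atol, dense_output=False,
        )
        if sol.status == -1:
            raise RuntimeError(
                f"Rayleigh-Plesset solver failed: {sol.message}; "
                f"last state r = {sol.y[0, -1] / NM_TO_M:.4g} nm, "
                f"v = {sol.y[1, -1] * NS_TO_S / NM_TO_M:.4g} nm/ns at t = {sol.t[-1] / NS_TO_S:.4g} ns"
            )
        times, radii, vels = sol.t, sol.y[0], sol.y[1]
        terminated = None
        if sol.status == 1:
            hit_min = len(sol.t_events[0]) > 0
            terminated = DISSOLUTION if hit_min else EMBOLISM
    else:
        rng = np.random.default_rng(params.seed)
        ts = [0.0]
        rs = [r0]
        vs = [v0]
        r, v = r0, v0
        terminated = None
        for k in range(len(t_eval) - 1):
            sol = solve_ivp(
                rhs, (t_eval[k], t_eval[k + 1]), [r, v], method="BDF",
                events=[ev_min, ev_max], rtol=1e-8, atol=atol,
            )
            if sol.status == -1:
                raise RuntimeError(f"Rayleigh-Plesset solver failed under noise: {sol.message}")
            r, v = sol.y[0, -1], sol.y[1, -1]
            if sol.status == 1:
                ts.append(sol.t[-1]); rs.append(r); vs.append(v)
                terminated = DISSOLUTION if len(sol.t_events[0]) else EMBOLISM
                break
            amp = (
                params.noise_amplitude
                if params.noise_amplitude is not None
                else thermal_noise_amplitude(r / NM_TO_M, params.temperature, params.eta)
            )
            v += amp * math.sqrt(dt) * rng.standard_normal() / (params.rho_liquid * r)
            ts.append(t_eval[k + 1]); rs.append(r); vs.append(v)
        times, radii, vels = np.array(ts), np.array(rs), np.array(vs)

    return BubbleTrajectory(
        times=times / NS_TO_S,
        radii=radii / NM_TO_M,
        velocities=vels * NS_TO_S / NM_TO_M,
        terminated=terminated,
    )


def classify_regime(
    traj: BubbleTrajectory,
    radii: Tuple[Optional[float], Optional[float]],
    *,
    band: float = 0.05,
    stable_radii: Optional[Sequence[float]] = None,
) -> str:
    """Label a trajectory growth / equilibration / embolism.

    embolism: the embolism bound was hit, or the terminal radius exceeds
    r_crit with positive terminal growth rate.  equilibration/growth: the
    terminal radius sits within ``band`` (relative) of a stable radius with
    a decaying oscillation envelope; called growth when the bubble was
    injected below the band (it grew up to equilibrium) and equilibration
    otherwise.  By default only r_eq is considered stable; a fitted gamma(r)
    whose noise wiggles insert secondary shallow minima can pass all of its
    stable radii via ``stable_radii``.  Anything else is labelled ambiguous,
    with diagnostics on the trajectory.
    """
    r_eq, r_crit = radii
    r = traj.radii
    if traj.terminated == EMBOLISM:
        return EMBOLISM
    if traj.terminated == DISSOLUTION:
        return DISSOLUTION
    r_end = r[-1]
    v_end = traj.velocities[-1]
    if r_crit is not None and r_end > r_crit and v_end > 0:
        return EMBOLISM
    candidates = list(stable_radii) if stable_radii else ([r_eq] if r_eq is not None else [])
    matched = next((rs for rs in candidates if abs(r_end - rs) <= band * rs), None)
    if matched is not None:
        dev = np.abs(r - matched)
        third = max(len(r) // 3, 1)
        decaying = dev[-third:].max() <= dev[:third].max() + 1e-12
        if decaying:
            return GROWTH if r[0] < (1.0 - band) * matched else EQUILIBRATION
    traj.diagnostics = (
        f"unclassified: r_end = {r_end:.4g} nm, v_end = {v_end:.4g} nm/ns, "
        f"r_eq = {r_eq}, r_crit = {r_crit}"
    )
    return AMBIGUOUS
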