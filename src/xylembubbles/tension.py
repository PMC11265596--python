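"""Kirkwood-Buff surface tension, surface-pressure isotherms and the gamma(r) fit.

The surface tension of a slab with two interfaces follows from the
anisotropy of the time-averaged pressure tensor,

    gamma = (Lz / 2) * < P_zz - (P_xx + P_yy) / 2 >,

with P_zz the component normal to the interfaces and Lz the (fixed, NVT)
box height.  With pressures in bar and Lz in nm, 1 bar nm = 0.1 mN/m.

Surface pressure is the reduction of the pure-water tension caused by the
lipid film, Pi(T) = gamma_water(T) - gamma_MD(T); negative values are
allowed (over-condensed films with gamma above the water reference give
negative Pi, and vice versa).

The dynamic surface tension of a bubble coated by a fixed number of lipids
is obtained by mapping area per lipid to a spherical radius,
r = sqrt(N * APL / 4 pi), and smoothing the isotherm with a sum of two
error functions

    gamma(r) = c + A1 erf((r - mu1)/s1) + A2 erf((r - mu2)/s2),

whose plateaus at both ends give the clamped values used outside the
fitted radius range.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf, expit
from scipy.stats import spearmanr  # noqa: F401  (re-exported convenience for analyses)

from .constants import BAR_NM_TO_MN_PER_M, GAMMA_WATER

__all__ = [
    "PressureTensorSeries",
    "IsothermPoint",
    "WaterReference",
    "GammaCurve",
    "kirkwood_buff_gamma",
    "surface_pressure",
    "build_isotherm",
    "apl_to_radius",
    "radius_to_apl",
    "fit_gamma_of_r",
]


@dataclass
class PressureTensorSeries:
    """Diagonal pressure-tensor samples from an NVT slab run."""

    times: np.ndarray  # ps
    p_xx: np.ndarray  # bar
    p_yy: np.ndarray  # bar
    p_zz: np.ndarray  # bar
    lz: float  # nm (fixed box height)
    temperature: float = 300.0  # K
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p_xx = np.asarray(self.p_xx, dtype=float)
        self.p_yy = np.asarray(self.p_yy, dtype=float)
        self.p_zz = np.asarray(self.p_zz, dtype=float)
        lens = {len(self.times), len(self.p_xx), len(self.p_yy), len(self.p_zz)}
        if len(lens) != 1 or len(self.times) < 1:
            raise ValueError("all series arrays must have equal length >= 1")
        if not self.lz > 0:
            raise ValueError("Lz must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class IsothermPoint:
    """(area per lipid, tension, surface pressure) at one temperature."""

    apl: float  # nm^2 per lipid
    gamma_md: float  # mN/m
    gamma_sd: float  # mN/m
    pi_md: float  # mN/m
    temperature: float  # K


@dataclass
class WaterReference:
    """Pure-water surface tension by temperature; exact lookup, no interpolation."""

    gamma_water: Dict[float, float] = field(default_factory=lambda: dict(GAMMA_WATER))

    def __call__(self, temperature: float) -> float:
        for t, g in self.gamma_water.items():
            if abs(t - temperature) < 1e-9:
                return g
        raise KeyError(
            f"no water-tension reference at T = {temperature} K; "
            f"known temperatures: {sorted(self.gamma_water)}"
        )


def kirkwood_buff_gamma(
    series: PressureTensorSeries,
    *,
    discard_ps: float = 10_000.0,
    n_blocks: int = 5,
) -> Tuple[float, float]:
    """Surface tension (mN/m) and block-averaged standard error from a tensor series.

    Samples with time < ``discard_ps`` are dropped (equilibration; default
    the first 10 ns).  The uncertainty is the standard error of ``n_blocks``
    contiguous block means, which absorbs the autocorrelation a raw
    per-sample standard error would ignore.
    """
    keep = series.times >= discard_ps
    if not np.any(keep):
        raise ValueError(
            f"no samples at or after the discard window ({discard_ps} ps); "
            f"series ends at {series.times.max()} ps"
        )
    dp = series.p_zz[keep] - 0.5 * (series.p_xx[keep] + series.p_yy[keep])
    gamma = BAR_NM_TO_MN_PER_M * (series.lz / 2.0) * float(dp.mean())
    m = len(dp)
    if m >= n_blocks >= 2:
        blocks = np.array_split(dp, n_blocks)
        bmeans = np.array([b.mean() for b in blocks])
        se_dp = bmeans.std(ddof=1) / math.sqrt(n_blocks)
    else:
        se_dp = dp.std(ddof=1) / math.sqrt(m) if m > 1 else 0.0
    sd = BAR_NM_TO_MN_PER_M * (series.lz / 2.0) * float(se_dp)
    return gamma, sd


def surface_pressure(
    gamma_md: float, temperature: float, ref: Optional[WaterReference] = None
) -> float:
    """Pi(T) = gamma_water(T) - gamma_MD(T), in mN/m.

    Raises KeyError for a temperature absent from the reference map: the
    water anchors are simulation-model constants, not interpolable data.
    """
    ref = ref or WaterReference()
    return ref(temperature) - gamma_md


def build_isotherm(
    series_list: Sequence[PressureTensorSeries],
    apl_list: Sequence[float],
    temperature: float,
    ref: Optional[WaterReference] = None,
    **kb_kwargs,
) -> List[IsothermPoint]:
    """Assemble a pressure:area isotherm, sorted ascending in APL."""
    if len(series_list) != len(apl_list):
        raise ValueError("series_list and apl_list must have equal length")
    apl_arr = np.asarray(apl_list, dtype=float)
    if len(np.unique(apl_arr)) < len(apl_arr):
        warnings.warn("duplicate APL values in isotherm; keeping all", stacklevel=2)
    points = []
    for series, apl in zip(series_list, apl_list):
        g, sd = kirkwood_buff_gamma(series, **kb_kwargs)
        points.append(
            IsothermPoint(
                apl=float(apl),
                gamma_md=g,
                gamma_sd=sd,
                pi_md=surface_pressure(g, temperature, ref),
                temperature=temperature,
            )
        )
    return sorted(points, key=lambda p: p.apl)


def apl_to_radius(apl: float, n_lipids: float) -> float:
    """Radius (nm) of a sphere coated by ``n_lipids`` at area per lipid ``apl`` (nm^2).

    4 pi r^2 = N * APL  =>  r = sqrt(N * APL / 4 pi).
    """
    apl = np.asarray(apl, dtype=float)
    if np.any(apl <= 0) or n_lipids <= 0:
        raise ValueError("apl and n_lipids must be positive")
    out = np.sqrt(n_lipids * apl / (4.0 * np.pi))
    return float(out) if out.ndim == 0 else out


def radius_to_apl(r: float, n_lipids: float) -> float:
    """Inverse of :func:`apl_to_radius`: APL = 4 pi r^2 / N."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or n_lipids <= 0:
        raise ValueError("r and n_lipids must be positive")
    out = 4.0 * np.pi * r**2 / n_lipids
    return float(out) if out.ndim == 0 else out


@dataclass
class GammaCurve:
    """Sum-of-two-error-functions dynamic surface tension gamma(r).

    Parameters are in mN/m (c, a1, a2) and nm (mu, sigma).  Outside
    ``domain`` the curve is clamped to its value at the nearest domain edge
    and the slope vanishes — bubbles outside the fitted radius range see the
    plateau tensions, never an extrapolation.  The clamp is smoothed over a
    ``clamp_width`` boundary layer (softplus, C-infinity) so that gamma and
    dgamma/dr stay continuous: a hard clamp makes the Rayleigh-Plesset
    right-hand side non-Lipschitz exactly where equilibria can sit.
    """

    c: float
    a1: float
    mu1: float
    s1: float
    a2: float
    mu2: float
    s2: float
    domain: Tuple[float, float]  # (r_lo, r_hi), nm
    n_lipids: float = 1e5
    clamp_width: Optional[float] = None  # nm; default 1% of the domain span
    covariance: Optional[np.ndarray] = None
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not (0 < lo < hi):
            raise ValueError("domain must satisfy 0 < r_lo < r_hi")
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValueError("erf widths must be positive")
        if self.clamp_width is None:
            self.clamp_width = 0.01 * (hi - lo)

    @classmethod
    def constant(cls, gamma: float, domain: Tuple[float, float], n_lipids: float = 1e5) -> "GammaCurve":
        """A static (radius-independent) surface tension."""
        return cls(c=gamma, a1=0.0, mu1=domain[0], s1=1.0, a2=0.0, mu2=domain[1], s2=1.0,
                   domain=domain, n_lipids=n_lipids)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.c, self.a1, self.mu1, self.s1, self.a2, self.mu2, self.s2])

    def _raw(self, r: np.ndarray) -> np.ndarray:
        return (
            self.c
            + self.a1 * erf((r - self.mu1) / self.s1)
            + self.a2 * erf((r - self.mu2) / self.s2)
        )

    def _smooth_clip(self, r: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """C-infinity clip of r into the domain; returns (r_clipped, d r_clipped / dr)."""
        lo, hi = self.domain
        w = self.clamp_width
        # softplus floor at lo, then softplus ceiling at hi
        x1 = (r - lo) / w
        rc1 = lo + w * np.logaddexp(0.0, x1)
        d1 = expit(x1)
        x2 = (hi - rc1) / w
        rc = hi - w * np.logaddexp(0.0, x2)
        d2 = expit(x2)
        return rc, d1 * d2

    def gamma(self, r) -> np.ndarray:
        """gamma(r) in mN/m for r in nm, clamped smoothly to the domain plateaus."""
        r = np.asarray(r, dtype=float)
        rc, _ = self._smooth_clip(r)
        out = self._raw(rc)
        return float(out) if out.ndim == 0 else out

    def dgamma_dr(self, r) -> np.ndarray:
        """Analytic d gamma / dr in mN/m per nm; vanishes outside the domain."""
        r = np.asarray(r, dtype=float)
        rc, drc = self._smooth_clip(r)
        two_over_sqrtpi = 2.0 / math.sqrt(math.pi)
        d = two_over_sqrtpi * (
            self.a1 / self.s1 * np.exp(-(((rc - self.mu1) / self.s1) ** 2))
            + self.a2 / self.s2 * np.exp(-(((rc - self.mu2) / self.s2) ** 2))
        )
        out = d * drc
        return float(out) if out.ndim == 0 else out

    def gamma_unclamped(self, r) -> np.ndarray:
        """The bare erf-sum without the domain clamp (used when fitting samples)."""
        out = self._raw(np.asarray(r, dtype=float))
        return float(out) if out.ndim == 0 else out

    def plateaus(self) -> Tuple[float, float]:
        """(left, right) asymptotic plateau tensions in mN/m (r -> 0 and r -> inf)."""
        return float(self._raw(np.float64(self.domain[0]))), float(
            self._raw(np.float64(self.domain[1]))
        )


def _erf_sum(r: np.ndarray, p: np.ndarray) -> np.ndarray:
    c, a1, mu1, s1, a2, mu2, s2 = p
    return c + a1 * erf((r - mu1) / s1) + a2 * erf((r - mu2) / s2)


def fit_gamma_of_r(
    isotherm: Sequence[IsothermPoint],
    n_lipids: float,
    *,
    n_restarts: int = 5,
    seed: int = 0,
) -> GammaCurve:
    """Fit gamma(r) = c + A1 erf((r-mu1)/s1) + A2 erf((r-mu2)/s2) to an isotherm.

    APL values are mapped to radii with :func:`apl_to_radius`; residuals are
    weighted by 1/sd when all points carry a positive gamma_sd.  The
    nonlinear least squares is restarted from ``n_restarts`` seeded
    perturbations of a data-driven initial guess and the best solution kept.

    Raises RuntimeError with per-restart diagnostics if no start converges.
    """
    if len(isotherm) < 7:
        raise ValueError("need >= 7 isotherm points to fit 7 parameters")
    pts = sorted(isotherm, key=lambda p: p.apl)
    r = np.array([apl_to_radius(p.apl, n_lipids) for p in pts])
    y = np.array([p.gamma_md for p in pts])
    sds = np.array([p.gamma_sd for p in pts])
    w = 1.0 / sds if np.all(sds > 0) else np.ones_like(y)

    span = r.max() - r.min()
    amp = (y.max() - y.min()) / 4.0
    # an erf step narrower than the data spacing is unidentifiable and fits
    # single noisy points; bound widths at the median sample spacing
    s_min = float(np.median(np.diff(r)))
    base = np.array(
        [y.mean(), max(amp, 1e-3), r.min() + 0.35 * span, span / 6.0,
         max(amp, 1e-3), r.min() + 0.65 * span, span / 6.0]
    )
    lb = np.array([-np.inf, -np.inf, r.min() - span, s_min, -np.inf, r.min() - span, s_min])
    ub = np.array([np.inf, np.inf, r.max() + span, 10 * span, np.inf, r.max() + span, 10 * span])

    def resid(p: np.ndarray) -> np.ndarray:
        return w * (_erf_sum(r, p) - y)

    rng = np.random.default_rng(seed)
    best = None
    diagnostics = []
    for k in range(n_restarts):
        p0 = base if k == 0 else base * (1 + 0.3 * rng.standard_normal(7))
        p0 = np.clip(p0, lb + 1e-6, ub - 1e-6)
        try:
            sol = least_squares(resid, p0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception as exc:  # pragma: no cover - qhull/solver pathologies
            diagnostics.append(f"restart {k}: {exc}")
            continue
        diagnostics.append(f"restart {k}: cost={sol.cost:.6g} status={sol.status}")
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("gamma(r) fit failed in all restarts:\n" + "\n".join(diagnostics))

    # order the two erf components by centre for a canonical parameterisation
    p = best.x.copy()
    if p[2] > p[5]:
        p = np.array([p[0], p[4], p[5], p[6], p[1], p[2], p[3]])

    jac = best.jac
    try:
        cov = np.linalg.inv(jac.T @ jac)
        dof = max(len(r) - 7, 1)
        cov *= 2 * best.cost / dof
    except np.linalg.LinAlgError:
        cov = None
    return GammaCurve(
        c=p[0], a1=p[1], mu1=p[2], s1=p[3], a2=p[4], mu2=p[5], s2=p[6],
        domain=(float(r.min()), float(r.max())),
        n_lipids=n_lipids,
        covariance=cov,
        fit_info={"cost": float(best.cost), "restarts": diagnostics},
    )
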