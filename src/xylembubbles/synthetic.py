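"""Synthetic monolayer frames, pressure-tensor series and isotherm samples.

Every downstream stage (phase classifier, pore estimator, Kirkwood-Buff
tension, gamma(r) fit, Rayleigh-Plesset regimes) is testable against these
generators because each one carries its ground truth in the returned
object's metadata:

* :func:`gen_hexagonal_patch` - a jittered triangular lattice emulating the
  liquid-condensed packing of a compressed monolayer;
* :func:`gen_disordered_patch` - random sequential addition with a minimum
  pair distance, emulating the liquid-expanded phase;
* :func:`punch_pore` - removes atoms from a disc, planting a pore of known
  radius;
* :func:`gen_pressure_tensor_series` - pressure-tensor samples whose time
  average encodes a prescribed surface tension through the two-interface
  slab relation gamma = (Lz/2) <P_zz - (P_xx + P_yy)/2>;
* :func:`gen_isotherm_samples` - noisy samples of an erf-sum gamma(APL)
  curve for exercising the dynamic-surface-tension fit;
* :func:`study_gamma_curve` - the reference ground-truth gamma(r) used by
  the analysis drivers, spanning ~0 mN/m (compressed film) to the pure
  water plateau across the radius range of a 1e5-lipid coating.

All generators are bit-reproducible under (spec, seed).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import erf

from .constants import GAMMA_WATER
from .phases import MonolayerFrame
from .tension import (
    GammaCurve,
    IsothermPoint,
    PressureTensorSeries,
    WaterReference,
    apl_to_radius,
    surface_pressure,
)

__all__ = [
    "SyntheticMonolayerSpec",
    "SyntheticTensorSpec",
    "gen_hexagonal_patch",
    "gen_disordered_patch",
    "punch_pore",
    "gen_pressure_tensor_series",
    "gen_isotherm_samples",
    "study_gamma_curve",
    "STUDY_N_LIPIDS",
    "STUDY_APL_RANGE",
]

#: Lipid count of the reference bubble coating.
STUDY_N_LIPIDS = 1e5
#: APL range (nm^2) spanned by the reference isotherm, from the equilibrium
#: density to the fully ruptured state.
STUDY_APL_RANGE = (0.55, 2.00)


@dataclass
class SyntheticMonolayerSpec:
    """Recipe for a synthetic monolayer frame.

    ``lattice_spacing`` is the triangular-lattice constant for the ordered
    generator and doubles as the minimum pair separation for the disordered
    one.  ``pore_discs`` are punched out after generation and recorded as
    planted ground truth.
    """

    box_lengths: Tuple[float, float] = (12.0, 12.0)  # nm
    n_atoms: int = 200  # target count (disordered generator)
    lattice_spacing: float = 0.5  # nm
    jitter_sd: float = 0.0  # nm
    pore_discs: List[Tuple[Tuple[float, float], float]] = field(default_factory=list)
    planted_labels: Optional[Sequence[str]] = None
    seed: int = 0


@dataclass
class SyntheticTensorSpec:
    """Recipe for a pressure-tensor series with known surface tension."""

    gamma_true: float = 70.5  # mN/m
    lz: float = 20.0  # nm
    n_samples: int = 30_000
    noise_sd: float = 50.0  # bar, i.i.d. per component per sample
    mean_pressure: float = 1.0  # bar
    temperature: float = 310.0  # K
    dt_ps: float = 2.0  # sample spacing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _apply_pores(frame: MonolayerFrame, spec: SyntheticMonolayerSpec) -> MonolayerFrame:
    for center, radius in spec.pore_discs:
        frame = punch_pore(frame, center, radius)
    return frame


def gen_hexagonal_patch(spec: SyntheticMonolayerSpec) -> MonolayerFrame:
    """Triangular lattice with Gaussian positional jitter, wrapped periodically.

    The box is snapped to the nearest lattice-commensurate size
    (nx * a, ny * a * sqrt(3)/2 with ny even); a requested box further than
    one lattice spacing from a commensurate one is rejected.  Every interior
    atom of the unjittered lattice has exactly six neighbours at the spacing.
    """
    a = spec.lattice_spacing
    if a <= 0:
        raise ValueError("lattice_spacing must be positive")
    if spec.jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    lx_req, ly_req = spec.box_lengths
    h = a * math.sqrt(3.0) / 2.0
    nx = int(round(lx_req / a))
    ny = 2 * int(round(ly_req / (2.0 * h)))
    if nx < 1 or ny < 2:
        raise ValueError(
            f"box {spec.box_lengths} is not commensurate with a triangular lattice of "
            f"spacing {a} nm: it cannot accommodate even one lattice cell"
        )
    lx, ly = nx * a, ny * h
    if abs(lx - lx_req) > a or abs(ly - ly_req) > a:
        raise ValueError(
            f"box {spec.box_lengths} is not commensurate with a triangular lattice of "
            f"spacing {a} nm within one spacing (nearest commensurate box: ({lx:.4f}, {ly:.4f}))"
        )
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xs = (ix + 0.5 * (iy % 2)) * a
    ys = iy * h
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    rng = np.random.default_rng(spec.seed)
    if spec.jitter_sd > 0:
        coords = coords + rng.normal(0.0, spec.jitter_sd, size=coords.shape)
    frame = MonolayerFrame(
        coords=coords,
        box_lengths=(lx, ly),
        metadata={
            "generator": "hexagonal",
            "lattice_spacing": a,
            "jitter_sd": spec.jitter_sd,
            "seed": spec.seed,
            "planted_pores": [],
        },
    )
    return _apply_pores(frame, spec)


def gen_disordered_patch(spec: SyntheticMonolayerSpec, *, max_attempts_per_atom: int = 200) -> MonolayerFrame:
    """Random sequential insertion with a minimum pair distance (periodic).

    Emulates the liquid-expanded phase: no six-fold cages, nearest-neighbour
    distances bounded below by ``lattice_spacing``.  If insertion saturates
    before reaching ``n_atoms`` the achieved count is kept with a warning.
    """
    d_min = spec.lattice_spacing
    if d_min < 0:
        raise ValueError("minimum separation must be >= 0")
    lx, ly = spec.box_lengths
    box = np.array([lx, ly])
    rng = np.random.default_rng(spec.seed)
    coords: List[np.ndarray] = []
    attempts_budget = max_attempts_per_atom * max(spec.n_atoms, 1)
    attempts = 0
    while len(coords) < spec.n_atoms and attempts < attempts_budget:
        attempts += 1
        cand = rng.uniform(0.0, 1.0, size=2) * box
        if coords:
            d = np.array(coords) - cand
            d -= box * np.round(d / box)
            if np.min(np.linalg.norm(d, axis=1)) < d_min:
                continue
        coords.append(cand)
    if len(coords) < spec.n_atoms:
        warnings.warn(
            f"random sequential insertion saturated at {len(coords)}/{spec.n_atoms} atoms "
            f"(min separation {d_min} nm in a {lx} x {ly} nm box)",
            stacklevel=2,
        )
    arr = np.array(coords) if coords else np.empty((0, 2))
    frame = MonolayerFrame(
        coords=arr,
        box_lengths=(lx, ly),
        metadata={
            "generator": "disordered",
            "min_separation": d_min,
            "requested_atoms": spec.n_atoms,
            "achieved_atoms": len(coords),
            "seed": spec.seed,
            "planted_pores": [],
        },
    )
    return _apply_pores(frame, spec)


def punch_pore(frame: MonolayerFrame, center: Tuple[float, float], radius: float) -> MonolayerFrame:
    """Remove all atoms within minimum-image distance < radius of ``center``.

    The planted pore is appended to the frame metadata for later recovery
    tests.  Raises if the pore would empty the frame entirely.
    """
    if radius <= 0:
        raise ValueError("pore radius must be positive")
    dist = frame.min_image_distances(center)
    keep = dist >= radius
    if frame.n_atoms > 0 and not np.any(keep):
        raise ValueError("pore covers every atom in the frame")
    meta = dict(frame.metadata)
    meta["planted_pores"] = list(meta.get("planted_pores", [])) + [
        (tuple(float(c) for c in center), float(radius))
    ]
    return MonolayerFrame(
        coords=frame.coords[keep],
        box_lengths=frame.box_lengths,
        time=frame.time,
        species=frame.species[keep] if frame.species is not None else None,
        leaflet_id=frame.leaflet_id,
        metadata=meta,
    )


def gen_pressure_tensor_series(spec: SyntheticTensorSpec) -> PressureTensorSeries:
    """Pressure-tensor samples whose expectation encodes ``gamma_true``.

    P_zz is centred at mean_pressure + D/2 and P_xx = P_yy at
    mean_pressure - D/2 with D = 2 gamma_true / (0.1 Lz) bar, so that
    (Lz/2) <P_zz - (P_xx+P_yy)/2> equals gamma_true mN/m exactly in
    expectation; each component carries independent Gaussian noise.
    """
    delta = spec.gamma_true / (0.1 * spec.lz / 2.0) / 2.0  # bar; D/2 with D = 20*gamma/Lz
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    noise = (
        rng.normal(0.0, spec.noise_sd, size=(3, n)) if spec.noise_sd > 0 else np.zeros((3, n))
    )
    p_zz = spec.mean_pressure + delta + noise[0]
    p_xx = spec.mean_pressure - delta + noise[1]
    p_yy = spec.mean_pressure - delta + noise[2]
    times = spec.dt_ps * np.arange(n)
    return PressureTensorSeries(
        times=times, p_xx=p_xx, p_yy=p_yy, p_zz=p_zz, lz=spec.lz,
        temperature=spec.temperature,
        metadata={"gamma_true": spec.gamma_true, "noise_sd": spec.noise_sd, "seed": spec.seed},
    )


def study_gamma_curve(temperature: float = 270.0, n_lipids: float = STUDY_N_LIPIDS) -> GammaCurve:
    """Ground-truth dynamic surface tension gamma(r) of the reference system.

    An erf-sum rising from ~0 mN/m (fully compressed coating) to the pure
    water plateau of the given temperature across the radii mapped from the
    APL range 0.55-2.00 nm^2 at the reference lipid count.  The supercooled
    curve sits at slightly larger radii (more condensed coating) than the
    310 K one, mirroring the measured temperature ordering of the isotherms.
    """
    ref = WaterReference()
    g_water = ref(temperature)
    lo = apl_to_radius(STUDY_APL_RANGE[0], n_lipids)
    hi = apl_to_radius(STUDY_APL_RANGE[1], n_lipids)
    amp = g_water / 4.0
    if abs(temperature - 270.0) < 1e-9:
        mu1, mu2 = 80.0, 106.0
    else:
        mu1, mu2 = 76.0, 102.0
    scale = math.sqrt(n_lipids / STUDY_N_LIPIDS)
    return GammaCurve(
        c=g_water / 2.0,
        a1=amp, mu1=mu1 * scale, s1=16.0 * scale,
        a2=amp, mu2=mu2 * scale, s2=22.0 * scale,
        domain=(lo, hi),
        n_lipids=n_lipids,
    )


def gen_isotherm_samples(
    curve_params: GammaCurve,
    apl_grid: Sequence[float],
    noise_sd: float,
    seed: int = 0,
    temperature: Optional[float] = None,
) -> List[IsothermPoint]:
    """Noisy isotherm samples of a known gamma(r) curve on an APL grid.

    Evaluates the (unclamped) erf-sum at r(APL) and adds i.i.d. Gaussian
    noise of sd ``noise_sd`` mN/m; the ground-truth curve is what the fit is
    later measured against.  The grid must be strictly increasing.
    """
    apl = np.asarray(apl_grid, dtype=float)
    if np.any(np.diff(apl) <= 0):
        raise ValueError("apl_grid must be strictly increasing")
    temperature = temperature if temperature is not None else _nearest_ref_t(curve_params)
    r = apl_to_radius(apl, curve_params.n_lipids)
    truth = np.atleast_1d(np.asarray(curve_params.gamma_unclamped(r)))
    rng = np.random.default_rng(seed)
    noisy = truth + (rng.normal(0.0, noise_sd, size=truth.shape) if noise_sd > 0 else 0.0)
    pts = []
    for a, g in zip(apl, noisy):
        pts.append(
            IsothermPoint(
                apl=float(a),
                gamma_md=float(g),
                gamma_sd=float(noise_sd) if noise_sd > 0 else 1.0,
                pi_md=surface_pressure(float(g), temperature),
                temperature=temperature,
            )
        )
    return pts


def _nearest_ref_t(curve: GammaCurve) -> float:
    """Reference temperature whose water tension best matches the curve's high plateau."""
    hi = curve.gamma(curve.domain[1])
    return min(GAMMA_WATER, key=lambda t: abs(GAMMA_WATER[t] - hi))
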