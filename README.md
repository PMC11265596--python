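# xylembubbles

Analysis pipeline for mixed lipid monolayers under tension and the dynamics
of the lipid-coated gas nanobubbles they enclose in plant xylem sap.

Sap in the water-conducting tissue of vascular plants is transported under
negative pressure, and in cold climates below its freezing point — a doubly
metastable liquid. Gas nanobubbles seeded into it through pit membranes are
coated by phospholipid/glycolipid monolayers, and whether such a bubble
stays stable or expands into an embolism (a gas-filled, hydraulically dead
conduit) is governed by the surface tension of its coating. This package
implements the post-simulation analysis chain for that problem, for
researchers in membrane biophysics and plant hydraulics:

* **2D phase classification** of monolayer tail-marker atoms into liquid
  condensed / liquid expanded / gas via a periodic Voronoi tessellation
  (LC: ≥ 6 neighbours within 0.8 nm; GAS: any neighbour beyond 1.5 nm;
  LE otherwise), plus grid-based largest-pore detection and 2D radial
  distribution functions;
* **Kirkwood–Buff surface tension** from pressure-tensor series,
  γ = (L_z/2)·⟨P_zz − (P_xx+P_yy)/2⟩, with block-averaged uncertainties,
  surface pressure Π(T) = γ_water(T) − γ(T), and pressure:area isotherms;
* **Dynamic surface tension** γ(r) = c + A₁erf((r−μ₁)/σ₁) + A₂erf((r−μ₂)/σ₂)
  fitted over the radius of a fixed-lipid-number spherical coating,
  r = √(N·APL/4π);
* **Nanobubble thermodynamics and dynamics**: Kelvin water potential,
  Laplace pressure, the classical nucleation theory barrier
  ΔG* = 16πγ³/(3p²), critical radii from dG/dr, and stochastic integration
  of the modified Rayleigh–Plesset equation
  ρ(r·r̈ + 3/2·ṙ²) = p_gas(r) − p − (2γ(r)/r)(1 − δ/r) − dγ/dr − 4η·ṙ/r,
  with growth / equilibration / embolism regime classification;
* **Synthetic data generators** with planted ground truth (lattice and
  disordered monolayers, punched pores, tensor series encoding a known γ,
  noisy isotherm samples), replacing molecular-dynamics output so every
  stage is testable end to end.

The scientific model and every numerical choice are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from xylembubbles import (GasState, RPParams, SyntheticMonolayerSpec, classify_phases,
                          classify_regime, critical_radii, gen_hexagonal_patch,
                          integrate_rp, largest_pore_radius, punch_pore,
                          study_gamma_curve)

# a condensed film with one 2 nm pore punched out
film = gen_hexagonal_patch(SyntheticMonolayerSpec(box_lengths=(12, 12),
                                                  lattice_spacing=0.5, seed=0))
film = punch_pore(film, center=(6, 6), radius=2.0)
phases = classify_phases(film)
pore = largest_pore_radius(film)
print(f"phases: LC {phases.fractions[0]:.2%}, LE {phases.fractions[1]:.2%}, "
      f"GAS {phases.fractions[2]:.2%}")
print(f"largest pore: {pore.radius:.2f} nm (planted 2.0 nm)")

# a 1e5-lipid coated bubble at 270 K under -1.5 MPa sap tension
curve = study_gamma_curve(270.0)
gas = GasState(p_ref=1.0, r_ref=45.0)           # 1 MPa gas load at 45 nm
cr = critical_radii(curve, -1.5, gas)
print(f"r_eq = {cr.r_eq:.1f} nm, r_crit = {cr.r_crit:.1f} nm, "
      f"r_cav = {cr.r_cavitation:.1f} nm")
traj = integrate_rp(RPParams(p_liquid=-1.5e6, temperature=270.0, r0=45.0,
                             p_gas0=1.0e6, gas_r_ref=45.0, t_end=100.0), curve)
print(f"bubble injected at 45 nm -> {classify_regime(traj, (cr.r_eq, cr.r_crit))}, "
      f"final radius {traj.radii[-1]:.1f} nm")
```

prints

```
phases: LC 95.12%, LE 3.58%, GAS 1.30%
largest pore: 1.86 nm (planted 2.0 nm)
r_eq = 74.1 nm, r_crit = 125.4 nm, r_cav = 96.8 nm
bubble injected at 45 nm -> growth, final radius 74.1 nm
```

Atoms ringing the punched pore are labelled GAS and the 40×40-grid estimator
recovers the pore within one grid-cell diagonal. The coated bubble has a
stable radius at 74 nm and — because dγ/dr ≠ 0 — a second critical radius at
125 nm, *above* the bare cavitation radius of 97 nm; injected below r_eq it
grows and settles at equilibrium. Injected between r_eq and r_crit it
shrinks back (equilibration); above r_crit it embolises.

## Analysis drivers

`analysis/` holds numbered narrative scripts that run the full study on
synthetic inputs and write tables under `results/`:

```sh
python analysis/01_synthesize_monolayers.py   # LC / LE / porous frames (GRO + CSV)
python analysis/02_phase_and_pores.py         # phase fractions vs area; pore recovery
python analysis/03_tension_isotherm.py        # KB isotherms at 270/310 K; gamma(r) fits
python analysis/04_bubble_regimes.py          # critical radii, three regimes, p scan
```

Step 04 reports the three dynamical regimes by injection radius and scans
the liquid pressure from −0.5 to −2.5 MPa at a 45 nm injection radius,
finding the equilibration window closed at −2.5 MPa.

A `xylembubbles` command-line tool exposes the same stages
(`synth | phases | pores | isotherm | fit | rp-sim`); see
`xylembubbles --help`.

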