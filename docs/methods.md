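# Methods

`xylembubbles` analyses the two-dimensional phase behaviour of mixed lipid
monolayers under tension and the dynamics of the lipid-coated gas
nanobubbles such monolayers coat in plant xylem sap. This note documents the
models, the synthetic data that stands in for molecular-dynamics output, the
numerical choices, and what the package's tests do and do not establish.

## Physical background

Sap in the xylem of vascular plants is transported under negative pressure
(water potential Ψ_water, set by evaporation at the leaf per the Kelvin
relation Ψ = (k_B T / v_m) ln a_w). Gas nanobubbles seeded through pit
membranes into this stretched liquid are coated by phospholipid/glycolipid
monolayers. The coating's surface tension γ sets the Laplace pressure
differential 2γ/r the bubble sustains; because the coating has a fixed lipid
count, γ depends on bubble radius through the area per lipid (APL), and the
bubble sits on a free-energy landscape with a stable equilibrium radius
r_eq, an embolism threshold r_crit, and — for a bare interface — the
classical nucleation theory (CNT) cavitation radius 2γ/|p| with barrier
16πγ³/(3p²).

## Monolayer phase classification

A frame is the set of xy positions of one tail-marker atom per lipid chain
in a periodic rectangular box. A Voronoi tessellation is built on a full
3×3 periodic tiling of the box (primary copy plus eight ghost images), so
atoms at the box edge see their periodic neighbours; adjacency of
primary-cell atoms then equals that of the infinite periodic point set.
Each atom is labelled, in this precedence order:

1. **LC** (liquid condensed) — at least 6 Voronoi neighbours within 0.8 nm;
2. **GAS** (pore edge) — otherwise, any Voronoi neighbour beyond 1.5 nm;
3. **LE** (liquid expanded) — otherwise.

Precedence matters: an atom at a pore edge that still has six close
neighbours is condensed. "Neighbour" means a Voronoi-adjacent atom, with
the minimum-image distance tested against the thresholds; an atom adjacent
to its own periodic image (very sparse frames) carries the image-translation
distance. Both cutoffs and the neighbour count are configurable. Duplicate
points (which the tessellation backend rejects) are perturbed
deterministically by at most 1e-9 nm with a warning.

The test oracle is an independent code path: Delaunay-triangulation
adjacency on the same tiling, with distances recomputed by brute force.
Implementation and oracle agree exactly on randomly generated frames.

**Largest pore radius.** The pore radius of a frame is the maximum over a
regular grid of cell centres (default 40×40) of the minimum-image distance
to the nearest atom, computed with a periodic k-d tree. The estimate is a
lower bound on the true largest-empty-circle radius and lies within one
grid-cell diagonal of it; tests verify both the planted-pore recovery and
the bound against a 400×400 dense grid.

**Trajectory statistics.** Per-frame scalars (LC fraction, pore radius) are
computed per leaflet, leaflets sharing a time point are averaged, the series
is sampled every 2.5 ns from t = 10 ns (nearest frame within half a stride),
and mean ± standard deviation over the retained frames is reported.

**2D radial distribution function.** Standard pair correlation normalised
by the ideal-gas annulus expectation under minimum image, defined for
r_max at most half the smaller box length.

## Surface tension and isotherms

For a slab with two interfaces in a box of fixed height L_z, the
Kirkwood–Buff surface tension is

    γ = (L_z / 2) · ⟨P_zz − (P_xx + P_yy)/2⟩,

with the 1/2 accounting for the two interfaces; 1 bar·nm = 0.1 mN/m. The
time average discards a configurable initial window (default the first
10 ns) and the uncertainty is the standard error of 5 contiguous block
means, which absorbs the autocorrelation of a real pressure series.

Surface pressure is Π(T) = γ_water(T) − γ(T) with the pure-water anchors
{270 K: 76.3, 310 K: 70.5} mN/m held as configuration constants (they come
from the water model, not from anything this package can compute); lookups
at other temperatures are refused rather than interpolated. Negative Π
(over-condensed films) is allowed.

**APL ↔ radius.** A spherical coating of N lipids at area per lipid APL has
r = sqrt(N·APL/4π). The reference coating uses N = 1e5, which places r_eq
in the 50–100 nm range observed for xylem nanobubbles.

**Dynamic surface tension γ(r).** The isotherm is smoothed with a sum of
two error functions,

    γ(r) = c + A₁ erf((r−μ₁)/σ₁) + A₂ erf((r−μ₂)/σ₂),

fitted by weighted (1/sd²) nonlinear least squares with five seeded
restarts; components are reported ordered by centre. Two numerical
safeguards matter:

* **Width floor.** An erf step narrower than the data spacing is
  unidentifiable — it can chase a single noisy point — so the widths are
  bounded below by the median radius spacing of the data.
* **Smooth plateau clamp.** Outside the fitted radius range the curve is
  clamped to its edge plateaus. The clamp is smoothed over a boundary layer
  of 1 % of the domain span (softplus composition, C∞), because a hard clamp
  makes dγ/dr discontinuous exactly where equilibrium radii can sit, which
  stalls the stiff ODE integrator. `plateaus()` reports the asymptotic
  values; the analytic dγ/dr includes the clamp's chain rule and matches
  finite differences everywhere.

## Bubble free energy and critical radii

Differentiating the Gibbs free energy of a coated bubble of radius r gives

    dG/dr = 8πr·γ(r) + 4πr²·dγ/dr + 4πr²·(p − p_gas(r)),

with p the liquid pressure and p_gas(r) = p_ref·(r_ref/r)^(3κ) the
polytropic internal gas pressure (κ = 1.4, slightly non-isothermal). Two
limits are enforced as tests: with dγ/dr = 0 the roots satisfy the Laplace
balance p_gas − p = 2γ/r at machine precision, and with no gas the
stationary point reproduces the CNT radius and barrier.

Stationary radii are located by bracketing sign changes of dG/dr on a
log-spaced scan (default 4000 points over 0.3×–5× the curve domain) and
polishing with Brent bisection. A −→+ crossing is a minimum of G (stable),
+→− a maximum (unstable). r_eq is the smallest stable root; r_crit is the
**outermost** unstable root above it — under tension dG/dr < 0 as r → ∞, so
the last root is the barrier beyond which growth runs away, and this choice
is robust to the small stable/unstable wiggle pairs a noisy fitted curve can
insert below it. r_cavitation is the CNT radius computed from the curve's
large-r plateau. An empty root set is returned with a diagnostic (the
extreme-negative-pressure regime).

## Rayleigh–Plesset integration

The radius obeys the modified Rayleigh–Plesset equation

    ρ(r·r̈ + 3/2·ṙ²) = p_gas0(r0/r)^(3κ) − p − (2γ(r)/r)(1 − δ/r)
                        − dγ/dr − 4η·ṙ/r  [+ noise],

whose static limit is consistent with dG/dr above. δ = +0.0316 nm is the
Tolman length (first-order curvature correction, applied multiplicatively
on the Laplace term; positive, appropriate for bubbles under negative
pressure, and numerically minor at 50–150 nm). η(T) is a supercooled-water
power law η = η₀(T/T_s − 1)^(−g) with T_s = 225.66 K and (η₀, g) solved
exactly from the anchors η(270 K) = 2.00e-3 and η(310 K) = 0.69e-3 Pa·s;
ρ = 1000 kg/m³.

The ODE is integrated in SI units as a first-order system with the stiff
implicit multistep BDF scheme on a fixed 10 ps output grid (the solver may
substep adaptively), with terminal events at r_min = 1 nm (dissolution) and
r_max = 10× the curve's largest fitted radius (embolism). `p_gas0` defaults
to the Laplace-balanced internal pressure at the injection radius,
2γ(r0)/r0 + p, clamped at zero if negative; a separate gas reference radius
lets several injection radii share one gas load.

**Thermal noise.** Optional, seeded, added as a velocity kick per output
step (Euler–Maruyama splitting around the deterministic BDF solve). The
default amplitude is fluctuation–dissipation consistent with the RP
friction: the friction force is 16πηr·ṙ, so the stochastic pressure has
spectral amplitude sqrt(2 k_B T η / (π r³)); the amplitude is an explicit
parameter and can be overridden. With noise off, trajectories are
bit-reproducible and seed-independent.

**Regime classification.** A trajectory is labelled *embolism* if it hit
the growth bound or ends above r_crit still growing; *growth* or
*equilibration* if it ends within ±5 % (configurable) of a stable radius
with a decaying oscillation envelope — growth when injected from below that
band, equilibration otherwise; anything else is *ambiguous*, never silently
coerced. When a fitted curve carries wiggle-induced secondary minima, all
stable roots may be supplied as candidate equilibria.

## Synthetic data: what it emulates and what it does not

No monolayer trajectories or pressure series are shipped; every analysis
input is generated with a known ground truth that travels in the object's
metadata.

* **LC-like frames** — triangular lattice (box snapped to the nearest
  commensurate size, rejected if the snap exceeds one spacing) with
  Gaussian positional jitter.
* **LE-like frames** — random sequential insertion with a minimum pair
  separation (the `lattice_spacing` field doubles as that separation);
  saturation short of the target count is reported, not hidden.
* **Pores** — discs punched from a frame and recorded as planted truth.
* **Pressure-tensor series** — P_zz and P_xx = P_yy offset so that the
  Kirkwood–Buff average equals a prescribed γ exactly in expectation, with
  i.i.d. Gaussian noise per component (50 bar by default, sampled every
  2 ps). Real MD series are autocorrelated; block averaging is exercised on
  white noise, so the uncertainty machinery is tested but its calibration
  against correlated data is not.
* **Isotherm samples** — the reference γ(r) evaluated on an APL grid plus
  Gaussian noise of 2 mN/m, the scale of the measured isotherm error bars.

**Reference study conditions.** The ground-truth γ(r) at 270 K is an
erf-sum rising from ≈3 mN/m (compressed film) to ≈75 mN/m (bare interface)
over the radii mapped from APL 0.55–2.00 nm² at N = 1e5 (r ≈ 66–126 nm):
c = 38.15, A₁ = A₂ = 19.075 mN/m, μ = 80/106 nm, σ = 16/22 nm; the 310 K
curve uses the 70.5 mN/m plateau with centres shifted 4 nm lower (the
warmer film is less condensed). The transition widths were fixed by a
design calculation so the landscape reproduces the qualitative structure of
the modelled system: at p = −1.5 MPa, r_eq ≈ 74 nm and r_crit ≈ 125 nm with
r_crit **above** r_cavitation ≈ 100 nm (the coating-induced second critical
radius), and the maximum tension the coating can stabilise is ≈2.26 MPa, so
a 45 nm bubble settles for p ≥ −2.0 MPa and embolises at −2.5 MPa. The gas
load is 1.0 MPa referenced at 45 nm (the total insertion-pressure target of
the simulated gas mixture at the scan's injection radius). Bubble dynamics
at these scales are strongly overdamped at 270 K, so the window closes by
root disappearance rather than inertial overshoot.

These generators exercise the estimators' contracts (planted-truth
recovery, oracle equivalence, limit recovery); passing tests demonstrate
correctness of the analysis machinery, not fidelity of any particular lipid
system — lateral diffusion, gas exchange, lipid packing energetics and
autocorrelated pressure fluctuations are all outside the model, as is any
claim about absolute timescales of the bubble dynamics.

## Problem sizes

Defaults keep every stage light: frames of a few hundred atoms, tensor
series of 3×10⁴ samples, 25-point isotherms, 100 ns trajectories at 10 ps
output steps. The full analysis sequence (scripts 01–04) and the test suite
each run in well under a minute on one CPU core.

## Known limitations

* The GAS label depends on Voronoi adjacency, which for extremely sparse
  frames includes self-image neighbours; interpretation below ~10 atoms per
  box is geometric rather than physical.
* The pore estimator reports the largest pore only; multi-pore statistics
  reduce to the maximum per frame, averaged over frames.
* The erf-sum fit covariance is a local Gauss–Newton estimate; with 7
  parameters and 25 points the two components are weakly identified, which
  is why the width floor exists.
* The noise term ignores the radius dependence of the effective mass within
  a step and is first-order (Euler–Maruyama) in the stochastic part.
* No gas or lipid transport to the interface: trajectories indicate the
  direction and stability structure of the dynamics, not chemical-time
  kinetics.
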