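#!/usr/bin/env python
"""Rayleigh-Plesset dynamics of a lipid-coated nanobubble at 270 K.

Loads the fitted gamma(r) from step 03 (results/gamma_curve_270K.json; falls
back to the reference curve if missing), locates the critical radii at
p = -1.5 MPa, integrates trajectories injected below r_eq, between r_eq and
r_crit, and above r_crit, then scans p from -0.5 to -2.5 MPa at a fixed
45 nm injection radius to find where the equilibration window closes.
Writes results/rp_trajectories.csv and results/rp_summary.json.
"""
import argparse
import json
import os

import numpy as np
import pandas as pd

from xylembubbles import (
    GasState,
    RPParams,
    classify_regime,
    critical_radii,
    integrate_rp,
    study_gamma_curve,
)
from xylembubbles.bubble import EMBOLISM
from xylembubbles.io import curve_from_dict


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--curve", default="results/gamma_curve_270K.json")
    args = ap.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)

    if os.path.exists(args.curve):
        with open(args.curve) as fh:
            curve = curve_from_dict(json.load(fh))
        print(f"using fitted curve {args.curve}")
    else:
        curve = study_gamma_curve(270.0)
        print("fitted curve not found; using the reference gamma(r)")

    gas = GasState(p_ref=1.0, r_ref=45.0, kappa=1.4)
    cr = critical_radii(curve, -1.5, gas)
    print(f"p = -1.5 MPa: r_eq = {cr.r_eq:.1f} nm (stable), "
          f"r_crit = {cr.r_crit:.1f} nm (embolism threshold), "
          f"r_cavitation = {cr.r_cavitation:.1f} nm (bare CNT radius)")

    frames = []
    regimes = {}
    stable_roots = [r for r, kind in cr.roots if kind == "stable"]
    for tag, r0 in (("below_r_eq", 45.0),
                    ("between", 0.5 * (cr.r_eq + cr.r_crit)),
                    ("above_r_crit", 1.15 * cr.r_crit)):
        traj = integrate_rp(
            RPParams(p_liquid=-1.5e6, temperature=270.0, r0=r0, p_gas0=1.0e6,
                     gas_r_ref=45.0, t_end=100.0),
            curve,
        )
        regime = classify_regime(traj, (cr.r_eq, cr.r_crit), stable_radii=stable_roots)
        regimes[tag] = {"r0_nm": r0, "regime": regime, "r_final_nm": float(traj.radii[-1])}
        print(f"  r0 = {r0:6.1f} nm ({tag:>12s}) -> {regime:13s} "
              f"(final radius {traj.radii[-1]:.1f} nm)")
        frames.append(pd.DataFrame({"case": tag, "t_ns": traj.times,
                                    "r_nm": traj.radii, "v_nm_per_ns": traj.velocities}))
    pd.concat(frames).to_csv(os.path.join(args.out_dir, "rp_trajectories.csv"), index=False)

    scan = []
    closing = None
    for p in (-0.5, -1.0, -1.5, -2.0, -2.5):
        cr_p = critical_radii(curve, p, gas)
        traj = integrate_rp(
            RPParams(p_liquid=p * 1e6, temperature=270.0, r0=45.0, p_gas0=1.0e6,
                     gas_r_ref=45.0, t_end=150.0),
            curve,
        )
        lab = classify_regime(traj, (cr_p.r_eq, cr_p.r_crit))
        scan.append({"p_MPa": p, "regime": lab,
                     "r_eq_nm": cr_p.r_eq, "r_crit_nm": cr_p.r_crit})
        if lab == EMBOLISM and closing is None:
            closing = p
    print("pressure scan at r0 = 45 nm:",
          ", ".join(f"{s['p_MPa']} MPa -> {s['regime']}" for s in scan))
    print(f"the equilibration window closes at p = {closing} MPa")

    summary = {"critical_radii_minus1p5MPa":
               {"r_eq_nm": cr.r_eq, "r_crit_nm": cr.r_crit, "r_cavitation_nm": cr.r_cavitation},
               "regimes": regimes, "pressure_scan": scan,
               "window_closing_pressure_MPa": closing}
    with open(os.path.join(args.out_dir, "rp_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
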