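"""Physical constants and unit conversions.

Interface units throughout the package are nm, mN m^-1, bar, MPa and K;
the Rayleigh-Plesset integrator works in SI internally.
"""

#: Boltzmann constant, J K^-1 (exact, 2019 SI).
K_B = 1.380649e-23

#: Molecular volume of liquid water, m^3 (18.015 g/mol at ~1 g/cm^3).
V_M_WATER = 2.99e-29

#: Liquid water density used in the bubble inertia terms, kg m^-3.
RHO_WATER = 1000.0

#: Pure-water (TIP4P/Ice) surface tension reference, K -> mN m^-1.
GAMMA_WATER = {270.0: 76.3, 310.0: 70.5}

#: 1 bar * 1 nm = 1e5 Pa * 1e-9 m = 1e-4 N/m = 0.1 mN/m.
BAR_NM_TO_MN_PER_M = 0.1

#: mN m^-1 -> N m^-1
MN_PER_M_TO_SI = 1e-3

#: nm -> m
NM_TO_M = 1e-9

#: MPa -> Pa
MPA_TO_PA = 1e6

#: ns -> s and ps -> s
NS_TO_S = 1e-9
PS_TO_S = 1e-12
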