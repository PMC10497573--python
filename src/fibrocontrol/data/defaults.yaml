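# Default parameter set: published constants for the homogenized
# myofibroblast diffusion model of idiopathic pulmonary fibrosis.
# Units: cm, day, g/cm^3; controls dimensionless.
D_m: 1.47e-5          # myofibroblast diffusion coefficient, cm^2/day
d_m: 1.66e-2          # myofibroblast death rate, 1/day
lambda_mfT: 1.2e-1    # activation rate due to TGF-beta, 1/day
lambda_mfG: 1.2e-1    # activation rate due to PDGF, 1/day
K_TGF: 1.0e-10        # TGF-beta saturation constant, g/cm^3
K_G: 1.5e-8           # PDGF saturation constant, g/cm^3
f: 4.75e-3            # fibroblast density in the damaged region, g/cm^3
m0: 8.5e-3            # initial myofibroblast density, g/cm^3
T_GF0: 2.51e-12       # initial activated TGF-beta concentration, g/cm^3
G0: 0.58e-3           # initial activated PDGF concentration, g/cm^3
a: 0.11               # homogenized diffusion coefficient (dimensionless)
gamma: 0.3702623906705539   # = 127/343, homogenized coefficient
domain: [0.3, 0.6]    # damaged interval per dimension, cm
t_f: 350.0            # control horizon, days
t_end_sim: 400.0      # forward-simulation horizon, days
N: 32                 # spectral order
n_steps: 10000        # Euler steps over the horizon
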