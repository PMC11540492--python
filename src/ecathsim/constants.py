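"""Physical constants and numerical guards shared across the package."""

FARADAY = 96485.33212  # C/mol
R_GAS = 8.31446261815324  # J/(mol K)
R_KCAL = 1.9872e-3  # kcal/(mol K), for activation energies quoted in kcal/mol

T_REF_DIFFUSION = 298.0  # K, reference for the T^(3/2) diffusivity scaling
T_HUB_DEFAULT = 298.15  # K (25 C): hub and Luer connector
T_TUBE_DEFAULT = 310.15  # K (37 C): implanted tube

C_REF = 1000.0  # mol/m^3, 1 M standard state used in Nernst reaction quotients

# Concentration floor applied inside logarithms and reaction quotients only;
# the solver state itself is never clamped.
EPS_CONC = 1e-12  # mol/m^3

# Cap on Butler-Volmer exponent arguments; never binds at operating potentials.
EXP_CAP = 50.0

MINUTE = 60.0  # s
HOUR = 3600.0  # s
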