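"""Physical constants and standard solvent presets.

Internal computations are in cgs units (cm, g, s, poise, erg); interfaces
use the field's reporting units: Å, Å⁻¹, Da, Svedberg (1 S = 1e-13 s),
cm²/s, kJ/mol, molar.
"""

# CODATA 2018 exact values
AVOGADRO = 6.02214076e23  # mol^-1
BOLTZMANN_ERG = 1.380649e-16  # erg/K
GAS_CONSTANT_KJ = 8.31446261815324e-3  # kJ/(mol K)

# water at 20 °C
WATER20_DENSITY = 0.99823  # g/mL
WATER20_VISCOSITY = 0.01002  # poise (1.002 cP)

# water at 4 °C (used for cold-room AUC runs)
WATER4_DENSITY = 0.99997  # g/mL
WATER4_VISCOSITY = 0.01567  # poise

SVEDBERG = 1e-13  # s
CM_PER_ANGSTROM = 1e-8
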