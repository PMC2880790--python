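"""Sedimentation-equilibrium mass analysis of a simulated truncated core.

Simulates radial interference profiles at 3000 rpm and 4 °C over the
6.8–7.25 cm window for a 1.65 MDa core carrying a 1% trace of a
double-mass aggregate, fits one- and two-species exponential models, and
extrapolates 1/M_app over loading concentration to the infinite-dilution
mass Mw⁰.
"""

import numpy as np

from pdccore import (extrapolate_Mw0, fit_se, rpm_to_omega, simulate_se)

OMEGA, T, RHO, VBAR = rpm_to_omega(3000.0), 277.15, 1.0, 0.746
R_GRID = np.linspace(6.8, 7.25, 80)
M_TRUE = 1.65e6

ds = simulate_se([(M_TRUE, VBAR, 0.297), (2 * M_TRUE, VBAR, 0.003)],
                 OMEGA, T, RHO, R_GRID, noise_sd=0.005, seed=42,
                 baseline=0.1)
one = fit_se(ds, VBAR, RHO, n_species=1)
two = fit_se(ds, VBAR, RHO, n_species=2)
print(f"1-species fit: M = {one.masses[0] / 1e6:.2f} MDa, rms {one.rms:.4f}")
print(f"2-species fit: M = {two.masses[0] / 1e6:.2f} MDa "
      f"({100 * two.fractions[0]:.1f}%) + {two.masses[1] / 1e6:.2f} MDa "
      f"({100 * two.fractions[1]:.1f}%), rms {two.rms:.4f}")
print("the two-species model improves the fit by "
      f"{one.rms / two.rms:.0f}× in rms residual\n")

# apparent mass vs loading concentration → infinite-dilution mass
concs = np.array([0.2, 0.4, 0.8, 1.6])
mapps = []
for i, c in enumerate(concs):
    d = simulate_se([(M_TRUE * (1 - 0.01 * c), VBAR, 0.3 * c)], OMEGA, T,
                    RHO, R_GRID, noise_sd=0.005, seed=100 + i, baseline=0.1,
                    loading_concentration=c)
    mapps.append(fit_se(d, VBAR, RHO, 1).masses[0])
mw0, err = extrapolate_Mw0(concs, mapps)
print(f"Mw⁰ (1/Mapp → 0 concentration) = {mw0 / 1e6:.2f} ± "
      f"{err / 1e6:.2f} MDa (truth 1.65 MDa)")
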