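"""Build synthetic dodecahedral core models for the competing stoichiometries.

Constructs the substitution-model (48 E2 + 12 E3BP), addition-model
(60 E2 + 12 E3BP face clusters) and E2-only cores, plus an "armed"
full-length variant with flexible N-terminal chains, and prints their
chain census and overall dimensions.  The truncated-core envelope spans
≈300 Å; the arms raise the maximum dimension to ≈480 Å and account for
roughly 40% of it.
"""

from pdccore import ArmSpec, AssemblySpec, add_flexible_arms, build_core_model

for stoich in ("substitution_48_12", "addition_60_12", "E2_only_60"):
    model = build_core_model(AssemblySpec(stoichiometry_model=stoich, seed=1))
    print(f"{stoich:20s} census={model.chain_census()}  "
          f"Dmax={model.dmax():6.1f} Å  Rg={model.radius_of_gyration():6.1f} Å")

core = build_core_model(AssemblySpec(seed=1))
armed = add_flexible_arms(core, ArmSpec(), seed=2)
frac = (armed.dmax() - core.dmax()) / armed.dmax()
print(f"\nwith flexible arms:  Dmax={armed.dmax():6.1f} Å "
      f"(arms contribute {100 * frac:.0f}% of the overall dimension)")
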