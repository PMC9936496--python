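"""Equilibrium constants at 20 C from fitted unfolding parameters.

Evaluates the anchored Gibbs-Helmholtz dimer model for the dark and
340 nm photostationary states of the phenylglycine-azobenzene coiled
coil and prints the unfolding/folding constants and the light-induced
fold change in binding affinity.
"""

from azocoil import thermo
from azocoil.thermo import UnfoldingParams, celsius_to_kelvin

STATES = {
    "dark":   UnfoldingParams(dH0=285.2, T0=celsius_to_kelvin(113.0),
                              dCp=2.80),
    "340 nm": UnfoldingParams(dH0=236.0, T0=celsius_to_kelvin(110.5),
                              dCp=2.15),
}

T20 = celsius_to_kelvin(20.0)
ku = {}
for label, params in STATES.items():
    k = thermo.unfolding_constant(params, T20)
    ku[label] = k["Ku"]
    print(f"{label:>7s}: dG = {thermo.gibbs_free_energy(params, T20):6.2f} "
          f"kJ/mol, Ku = {k['Ku'] * 1e6:5.2f} uM, Kf = {k['Kf']:.2e} /M")

print(f"fold change (dark -> 340 nm): {ku['340 nm'] / ku['dark']:.2f}x "
      "weaker binding after trans->cis isomerization")
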