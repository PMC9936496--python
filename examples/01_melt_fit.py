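"""Global two-state fit of multi-concentration CD melting curves.

Generates four noisy synthetic melts of a heterodimeric coiled coil
(total concentrations 10-100 uM), fits the shared thermodynamic triple
(dH0, T0, dCp) with per-curve linear baselines, and compares candidate
stoichiometries by AIC.
"""

from azocoil import synthetic, thermo

curves, truth = synthetic.gen_melt_curves()
print(f"simulated {len(curves)} curves, truth: "
      f"dH0={truth['dH0']} kJ/mol, T0={truth['T0']} K, "
      f"dCp={truth['dCp']} kJ/mol/K")

fit = thermo.fit_global(curves)
p = fit.params
print(f"fitted:  dH0={p.dH0:.1f} kJ/mol, T0={p.T0:.2f} K, "
      f"dCp={p.dCp:.2f} kJ/mol/K")
print(f"Ku(20 C) = {fit.Ku20 * 1e6:.3f} uM,  Kf(20 C) = {fit.Kf20:.3e} /M")

ranked = thermo.compare_models(curves, [2, 3, 4])
print("model comparison (AIC, lower is better):")
for r in ranked:
    print(f"  n = {r.params.stoichiometry}: AIC = {r.aic:.1f}")
print(f"-> the data were generated by a dimer; the fit selects "
      f"n = {ranked[0].params.stoichiometry}.")

ci = thermo.bootstrap_confidence(fit, curves, n_boot=100, seed=0)
print("95% bootstrap intervals:",
      {k: (round(v[0], 2), round(v[1], 2)) for k, v in ci.items()})
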