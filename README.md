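# azocoil

Analysis toolkit for **azobenzene-photoswitchable coiled coils**: the
thermodynamics of light-controlled coiled-coil binding, the photochemistry
of the azobenzene switch, and the trajectory-distance statistic that links
the two.

A heterodimeric coiled coil (the designed E/K pair, (EIAALEK)₃ +
(KIAALKE)₃) carrying an azobenzene amino acid in its hydrophobic core can
be switched between a tight-binding dark (trans) state and a weaker-binding
UV-irradiated (cis) state. Quantifying that switch requires three
computations, each of which this package implements as tested, reusable
library code:

1. **Two-state unfolding thermodynamics** (`azocoil.thermo`).
   The unfolding free energy follows the Gibbs–Helmholtz expansion anchored
   at the reference temperature *T*° where ΔG = 0 and *K*ᵤ = *K*f = 1:

   ΔG<sub>u</sub>(T) = ΔH°·(1 − T/T°) + ΔC<sub>p</sub>·[(T − T°) − T·ln(T/T°)]

   with *K*ᵤ(T) = exp(−ΔG<sub>u</sub>/RT) in mol/L closing the heterodimer
   mass balance *K*ᵤ = (1−f)²·C<sub>t</sub>/(2f) (C<sub>t</sub> = total
   monomer concentration). Melting curves at several concentrations are
   fitted globally — one shared (ΔH°, *T*°, ΔC<sub>p</sub>), per-curve
   linear baselines — and candidate stoichiometries are ranked by AIC.
   Residual-bootstrap confidence intervals are provided.

2. **Photoswitch kinetics** (`azocoil.photokinetics`).
   Mean residue ellipticity [θ] = 100·θ<sub>obs</sub>/(c·n·l); isomer
   composition from single-wavelength absorbance unmixing or replicate
   HPLC peak areas; first-order thermal cis→trans relaxation fits
   (t<sub>½</sub> = ln2/k); and a phase-wise photokinetics simulator whose
   photostationary state (PSS) per phase is the analytic fixed point
   f<sub>cis</sub>(∞) = k<sub>tc</sub>/(k<sub>tc</sub>+k<sub>ct</sub>+k<sub>relax</sub>).

3. **Trajectory distance changes** (`azocoil.trajectory`).
   For paired trans/cis trajectory ensembles, per-residue distances from
   the partner chain to the three azobenzene moieties (diazene, inner
   "ring 1", outer "ring 2") are averaged per replica and across replicas,
   and the normalized change Δ = (d̄<sub>cis</sub> − d̄<sub>trans</sub>)/d̄<sub>trans</sub>
   is flagged significant at |Δ| ≥ 0.2. Utilities cover 5 Å contact
   shells, heptad-register assignment (a–g) and RMSD to an ideal α-helix.

Two supporting modules complete the pipeline: `azocoil.ffparams` extracts
equilibrium bonded parameters (bonds/angles/dihedrals) around a new azo
nitrogen atom type from an optimized geometry and emits a GROMACS-style
block with the stiff cis/trans dihedral restraint (1000 kJ·mol⁻¹·rad⁻²),
and `azocoil.synthetic` generates every input with embedded ground truth
(melts, relaxation/cycling traces, paired toy trajectories), so the whole
analysis is testable without instrument data.

## Worked example

```python
from azocoil import synthetic, thermo

curves, truth = synthetic.gen_melt_curves()   # 4 noisy melts, 10-100 uM
fit = thermo.fit_global(curves)
print(fit.params.dH0, fit.params.T0, fit.params.dCp)
# 249.99 390.00 2.00            <- truth was (250, 390, 2.0)
print(fit.Ku20 * 1e6)           # 0.426 uM unfolding constant at 20 C
ranked = thermo.compare_models(curves, [2, 3, 4])
print([r.params.stoichiometry for r in ranked])   # [2, 3, 4] - dimer wins
```

The fitted triple reproduces the generating truth (enthalpy to <0.1%,
reference temperature to <0.01 K here), and AIC ranks the generating
dimer far ahead of trimer/tetramer alternatives. Evaluating the same
model at published fit parameters for the phenylglycine-azobenzene
system gives Ku(20 °C) = 0.72 μM (dark) vs 3.43 μM (340 nm PSS) — a
4.7-fold light-induced loss of binding affinity:

```sh
python examples/02_published_constants.py
```

The other `examples/*.py` scripts each demonstrate one capability
(global melt fitting, photoswitching analysis, trajectory distance
changes, force-field parameter extraction) and print a line explaining
the numbers.

A thin CLI wraps the config-driven pipeline:

```sh
azocoil --config pipeline.yaml --out run/ --seed 1
```

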