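# Methods

## Two-state unfolding model

The folded species is an n-mer (default: heterodimer of two distinct,
equimolar strands). Unfolding is two-state; the free energy uses the
Gibbs–Helmholtz expansion anchored at the reference temperature T°:

    dG_u(T) = dH0*(1 - T/T0) + dCp*[(T - T0) - T*ln(T/T0)]

* `dH0` — unfolding enthalpy at T0, kJ/mol. Typical fitted values for
  designed coiled coils fall in 150–300 kJ/mol.
* `T0` — the temperature where dG = 0 and Ku = Kf = 1 (standard state
  1 mol/L). This is *not* the apparent melting midpoint: for micromolar
  concentrations T0 lies several tens of kelvin above it.
* `dCp` — temperature-independent heat-capacity change of unfolding,
  kJ/mol/K.

This is the minimal three-parameter model consistent with an anchored
reference temperature; dCp = 0 recovers the van 't Hoff limit exactly.
Constants: R = 8.314 J/mol/K, K = °C + 273.15. Exponents are clamped at
±700 before exponentiation (clamped evaluations are flagged).

### Mass balance

`Ct` is the **total monomer concentration** (both strands summed).
For the equimolar heterodimer, Ku = [E][K]/[EK] = (1-f)^2*Ct/(2f), whose
folded-fraction root is the closed-form quadratic solution. General
n-mers (hetero: equimolar strands at Ct/n each; homo: single species)
are solved in x = ln f, where the implied ln Ku is strictly decreasing
and concave: eight vectorized bisection steps bracket the root and
safeguarded Newton polishes it, resolving f to ~1e-13 relative — the
dimer closed form and the generic solver agree to better than 1e-10
across a wide log grid of Ku/Ct. Extreme Ku values whose root lies
outside the floating bracket are pinned to 0 or 1.

### Global fitting

Melting curves are modeled as
signal(T) = f(T)*(aF + bF*T) + (1-f(T))*(aU + bU*T) with linear
folded/unfolded baselines per curve (standard CD-melt practice; the
baselines are expressed against T in kelvin). The fit shares
(dH0, T0, dCp) across curves and exploits that the baselines enter
linearly: the optimizer (scipy trust-region-reflective least squares)
sees only the three thermodynamic parameters, and the per-curve
baselines are profiled out by a 4-column linear solve inside the
residual (variable projection). Bounds: dH0 in [10, 3000] kJ/mol,
T0 in [273.15, 700] K, dCp in [0, 50] kJ/mol/K.

The profiled objective is a narrow ridge in (dH0, T0) — parameter pairs
whose implied apparent midpoint misses the observed one are heavily
penalized — so initialization walks along the ridge: the steepest-slope
temperature of the first curve estimates the apparent midpoint Tm, and
for each trial dH0 (100–600 kJ/mol) and dCp (1–3 kJ/mol/K) the T0 that
places the model midpoint (Ku(Tm) equal to the mass-balance value at
f = 1/2) at Tm is found by root bracketing; the cheapest ridge point
seeds the polish. The heuristic is overridable via the `init` argument.

Model comparison fits each candidate stoichiometry and ranks by AIC
computed under an i.i.d. Gaussian likelihood with profiled variance
(k = 3 shared + 4 per curve + 1); ties within 1e-9 go to the lower
stoichiometry. Raw residual sums are reported alongside.

Confidence intervals use a residual-resampling bootstrap: residuals are
pooled across curves, resampled with replacement, added back onto the
fitted model, and refitted starting from the fitted parameters;
intervals are the 2.5/97.5 percentiles. With 200 resamples the empirical
coverage of the 95% dH0 interval on the reduced synthetic design is
inside [0.90, 0.99] (checked by simulation in the test suite). All-zero
residuals produce degenerate zero-width intervals with a warning.

## Photoswitch kinetics

* Mean residue ellipticity uses [θ] = 100*θ_obs/(c*n*l) with θ_obs in
  mdeg, c in mM, n = number of peptide bonds, l in cm. The prefactor is
  exposed (`prefactor=`) because normalization conventions vary between
  instruments; n is an explicit input — for capped peptides the count
  includes the terminal amide linkages (a 21-residue capped peptide has
  22 backbone amides).
* Absorbance unmixing is single-wavelength and linear between a trans
  and a cis reference; values outside [-0.02, 1.02] are rejected as
  inconsistent references, slight overshoots are clipped with a warning.
  The dark state serves as the trans reference unless a measured
  dark-state composition is supplied.
* HPLC compositions: per-replicate fraction = area/(area sum); the
  reported deviation is half the max-min spread across replicates (the
  natural summary for 2–3 repeat injections), with the sample SD also
  recorded.
* Thermal relaxation fits y(t) = offset + amplitude*exp(-k*t) by
  nonlinear least squares; a flat series or a rate within 2 SE of zero
  raises "no decay detected" rather than returning a spurious half-life.
* Photokinetics: each illumination phase has constant rates, so the ODE
  df_cis/dt = k_tc*(1-f) - (k_ct+k_relax)*f is solved exactly as an
  exponential approach to the phase PSS — no numerical integrator, hence
  no step-size error. Run-to-PSS phases terminate strictly inside the
  1e-6 band (the closed-form duration targets half the tolerance).

## Trajectory distance statistic

Distances are measured in Å on ensembles of replicas sharing one
topology; no periodic imaging is applied (inputs are assumed whole).
The default residue↔moiety metric is the per-frame **minimum
heavy-atom pair distance** (the contact-analysis convention); a centroid
metric is available. Residue atom sets default to all heavy atoms with a
side-chain-only option. Replica averaging is time-mean per replica, then
unweighted mean and sample SD across replicas (a warning is issued if
replica lengths differ by more than 10%).

The normalized change is (mean_cis - mean_trans)/mean_trans — positive
means farther from the partner chain in the cis state — with
significance at |delta| >= 0.2 (the conventional cutoff for this
statistic); a pooled-mean denominator is available behind a flag.
Contact shells use a closed boundary (d <= 5.0 Å by default) over heavy
side-chain atoms. Helix RMSD superposes with the Kabsch algorithm
(proper rotations; the residual is evaluated on explicitly rotated
coordinates to avoid catastrophic cancellation near zero) against an
ideal α-helix (rise 1.5 Å/residue, 100°/residue twist) or a supplied
reference.

## Bonded-parameter extraction

Equilibrium values are measured directly from an input geometry: bond
lengths as Euclidean distances, angles at the central atom, dihedrals
with the IUPAC sign convention (cis = 0°, signed in (-180°, 180°]).
Only terms touching the filtered atom type (default `NX`, the azo
nitrogens) are retained. Force constants are never derived — they are
adopted from a user-supplied analog map keyed by direction-independent
atom-type tuples; a missing entry is an error naming the term. The
emitted GROMACS-style block is deterministically sorted and round-trips
byte-identically through the module's parser; the cis/trans restraint
line targets 180° (trans) or 0° (cis) with k = 1000 kJ/mol/rad².
The bundled azobenzene geometry and its analog force constants are
synthetic idealizations (textbook bond lengths, planar rings), suitable
for exercising the extraction machinery, not production simulation.

## Synthetic-data generators

Every generator returns its inputs plus a machine-readable truth record;
downstream recovery tests read the truth from the record only.

* **Melts**: four total concentrations (10/25/50/100 μM), 5–90 °C in
  1 °C steps, truth (dH0, T0, dCp) = (250 kJ/mol, 390 K, 2.0 kJ/mol/K),
  baselines aF = -30000, bF = 20, aU = -3000, bU = 5 (mean-residue-
  ellipticity units against T in K), Gaussian noise σ = 0.3 signal
  units. The concentrations and baselines are invented defaults in the
  range typical of designed coiled-coil CD experiments.
* **Relaxation**: half-life 1690 min, amplitude 0.913 (a cis-dominant
  photostationary state), sampled over three half-lives.
* **Cycling**: alternating UV/blue run-to-PSS phases; rate pairs put the
  UV PSS at ≈91% cis and the blue PSS at ≈8% cis with the slow thermal
  relaxation active throughout.
* **Toy trajectories**: two parallel ideal α-helices 9.5 Å apart carry
  the E/K heptad sequences with three pseudo-atoms per residue (Cα plus
  two radial side-chain atoms); a rigid pseudo-azobenzene (2-atom
  diazene, two 6-atom rings) sits at K-chain position 9 pointing toward
  chain E in trans; the cis state displaces the diazene 2 Å away from
  chain E and swings ring 2 by 120° back toward chain K. Three replicas
  of 100 frames add i.i.d. Gaussian jitter (σ = 0.25 Å per coordinate)
  with replica sub-seeds drawn from the master seed. The truth table is
  the distance-change statistic evaluated on the jitter-free geometry.

  This harness is deliberately **not** a physical simulation: it has no
  forces, no correlated motions, no unfolding termini and no solvent.
  Its only contract is that the ground-truth distances are known
  exactly, which is what makes the statistic testable. Passing tests
  demonstrate that the statistic recovers a constructed geometry change
  through sampling noise — not that any real trajectory shows these
  values. A consequence of the construction: ring 1 is identical
  between the two states, so its analytic change is exactly zero and a
  measured sign for ring-1 pairs is pure noise; recovery checks
  therefore compare significance flags for all pairs and signs only
  where the truth declares a significant change.

## Pipeline

The config-driven runner executes stages in dependency order
(generation before fitting), writes JSON/CSV artifacts under one run
directory, and ends with a manifest recording the config, seed, input
SHA-256 hashes and package version. All randomness funnels through the
single global seed, so identical config + seed reproduces artifacts
byte-identically. Schema violations abort with the offending key before
any stage runs; a stage failure still writes the manifest with the
partial results and the failed stage named.

## Problem sizes and determinism

The test suite runs reduced-size simulations chosen to exercise the
statistics rather than to maximize power: the repeated model-selection
check uses a two-concentration, 5 °C-step design over 50 seeds, and the
bootstrap coverage check uses 50 synthetic experiments × 200 resamples.
All stochastic tests fix their seeds; property-based tests run with
derandomized settings.

## Known limitations

* No kinetic (scan-rate-dependent) unfolding, no three-state
  intermediates, no spectral SVD: strictly two-state equilibrium.
* The absorbance unmixing assumes linearity at a single wavelength; no
  quantum yields or extinction-spectrum deconvolution.
* Trajectory analysis reads multi-model PDB only (one MODEL per frame,
  one file per replica); binary MD formats are out of contract.
* The mass-balance solver assumes equimolar strands for
  hetero-oligomers.
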